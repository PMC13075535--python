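{
  "comment": "Wheelchair reach and manoeuvring clearance bounds (mm) from four standards: IS-7454 (Indian wheelchair specification), CPWD (Central Public Works Department), CCD (Chief Commissioner-Disability) and ISO. Entries are a single bound, a [min, max] range, or null where the standard does not specify. direction: 'ge' means the computed reach must meet or exceed the bound; 'le' means the computed clearance envelope must fit within the bound.",
  "reach": {
    "forward_high": {"direction": "ge", "IS-7454": [1350, 1600], "CPWD": 1200, "CCD": 1200, "ISO": 1200},
    "forward_low": {"direction": "ge", "IS-7454": null, "CPWD": 400, "CCD": 400, "ISO": 400},
    "forward_obstructed_high": {"direction": "ge", "IS-7454": [715, 830], "CPWD": 1100, "CCD": 1100, "ISO": null},
    "lateral_high": {"direction": "ge", "IS-7454": [1350, 1770], "CPWD": 1300, "CCD": 1300, "ISO": null},
    "lateral_low": {"direction": "ge", "IS-7454": null, "CPWD": 250, "CCD": 250, "ISO": null},
    "lateral_obstructed_high": {"direction": "ge", "IS-7454": null, "CPWD": 1200, "CCD": 1200, "ISO": null}
  },
  "maneuvering": {
    "circular_turn_360": {"direction": "le", "IS-7454": 1500, "CPWD": [1500, 2000], "CCD": 1800, "ISO": 1500}
  }
}
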