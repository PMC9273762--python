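- name: stable
  drift: {}
  episode_hazard: 0.0
  driver_vitals: []
- name: respiratory_failure
  drift:
    SPO2: -0.8
    RR: 1.5
  episode_hazard: 0.02
  driver_vitals:
  - SPO2
  - RR
- name: sepsis_like
  drift:
    SBP: -2.5
    TEMP: -0.06
    HR: -1.2
  episode_hazard: 0.02
  driver_vitals:
  - SBP
  - TEMP
  - HR
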