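# Full-field ERG stimulus protocol.
#
# Flash strengths are photopic cd·m⁻²·s; background luminances are
# cd·m⁻² (scotopic / photopic).  "DA"/"LA" follow ISCEV nomenclature
# (dark-/light-adapted).  The X* stimuli are the xenon flash series used
# for rod/cone separation: each strength is delivered in the dark and on
# the dim blue rod-saturating background (30 scotopic, 1 photopic cd·m⁻²);
# pointwise subtraction of the blue-background (cone-driven) response from
# the dark (rod+cone) response isolates the dark-adapted rod response.
stimuli:
  - {label: "DA 0.01",   flash_strength: 0.01, background: dark,  mode: single_flash}
  - {label: "DA 3",      flash_strength: 3.0,  background: dark,  mode: single_flash}
  - {label: "DA 10",     flash_strength: 10.0, background: dark,  mode: single_flash}
  - {label: "X0.67-dark", flash_strength: 0.67, background: dark,  mode: single_flash}
  - {label: "X4-dark",    flash_strength: 4.0,  background: dark,  mode: single_flash}
  - {label: "X13-dark",   flash_strength: 13.0, background: dark,  mode: single_flash}
  - {label: "X67-dark",   flash_strength: 67.0, background: dark,  mode: single_flash}
  - {label: "X0.67-blue", flash_strength: 0.67, background: blue,  mode: single_flash}
  - {label: "X4-blue",    flash_strength: 4.0,  background: blue,  mode: single_flash}
  - {label: "X13-blue",   flash_strength: 13.0, background: blue,  mode: single_flash}
  - {label: "X67-blue",   flash_strength: 67.0, background: blue,  mode: single_flash}
  - {label: "LA 3",      flash_strength: 3.0,  background: white, mode: single_flash}
  - {label: "LA 30Hz",   flash_strength: 3.0,  background: white, mode: flicker_30hz}
backgrounds:
  dark:  {kind: dark,                scotopic: 0.0,  photopic: 0.0}
  blue:  {kind: blue_rod_saturating, scotopic: 30.0, photopic: 1.0}
  white: {kind: white_photopic,      scotopic: 0.0,  photopic: 30.0}
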