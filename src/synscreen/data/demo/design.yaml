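concentrations:
- 20.0
readouts:
- hoechst
- prestoblue
n_neg_controls_per_plate: 8
n_pos_controls_per_plate: 8
pos_control_label: CX-4945 20 uM
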