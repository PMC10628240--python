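# Worked humanization example: a murine anti-PD-L1 Fv (synthetic stand-in
# sequences; no deposited sequence or coordinates exist for the original
# case) together with a hand-transcribed framework-CDR contact summary of
# the kind a modeller reads off a predicted Fv structure at the 4.2 A
# analysis window.  The support entries are a text fixture, not measured
# from coordinates.
heavy:
  donor_id: anti-PDL1-VH-synthetic
  donor_sequence: >-
    QVQLVQSGAEVKKPGASVKVSCKASGYTFTTYGMSWVKQRPGQGLEWVGNIDPYYGGTTYNQFKVKATLTADTSTSTAYMELRSSLRSEDTACAGDGYRYSGFDYWGQGTLVTVSS
  acceptor: IGHV1-46*01
  support:
    - {fr_position: "38", cdr_position: "95", min_distance: 4.0, interaction_class: proximal}
    - {fr_position: "40", cdr_position: "96", min_distance: 4.1, interaction_class: proximal}
    - {fr_position: "48", cdr_position: "50", min_distance: 3.8, interaction_class: hydrophobic}
    - {fr_position: "66", cdr_position: "63", min_distance: 3.8, interaction_class: hydrophobic}
    - {fr_position: "66", cdr_position: "65", min_distance: 4.0, interaction_class: hydrophobic}
    - {fr_position: "67", cdr_position: "63", min_distance: 3.5, interaction_class: hydrophobic}
    - {fr_position: "67", cdr_position: "54", min_distance: 3.9, interaction_class: hydrophobic}
    - {fr_position: "69", cdr_position: "35", min_distance: 3.7, interaction_class: hydrophobic}
    - {fr_position: "71", cdr_position: "52", min_distance: 4.0, interaction_class: hydrophobic}
    - {fr_position: "78", cdr_position: "100", min_distance: 3.9, interaction_class: hydrophobic}
    - {fr_position: "82A", cdr_position: "100A", min_distance: 4.1, interaction_class: proximal}
    - {fr_position: "94", cdr_position: "101", min_distance: 3.6, interaction_class: hydrophobic}
light:
  donor_id: anti-PDL1-VL-synthetic
  donor_sequence: >-
    DIVMTQSPSSLSASVGDRVTITCRASENIYSYLAWYQQKPGKAPKLLIYNAKTRAEGVPDRFTGSGSGTDFTLTISSLQPEDFATYYCQHHYGTPLTFGQGTKVEIK
  acceptor: IGKV1-5*01
  support:
    - {fr_position: "3", cdr_position: "26", min_distance: 4.0, interaction_class: proximal}
    - {fr_position: "60", cdr_position: "50", min_distance: 4.1, interaction_class: proximal}
    - {fr_position: "63", cdr_position: "54", min_distance: 3.0, interaction_class: hydrogen_bond}
    - {fr_position: "70", cdr_position: "89", min_distance: 4.0, interaction_class: proximal}
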