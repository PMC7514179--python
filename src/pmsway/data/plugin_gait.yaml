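# Default marker configuration: Plug-in-Gait full-body set without hand markers
# (37 markers), reduced to the 28 bilaterally symmetric markers that survive
# left/right mirroring (wand/offset markers RBAK, L/RUPA, L/RFRM, L/RTHI, L/RTIB
# are asymmetrically placed and therefore omitted).
#
# relative_segment_mass: Winter-style segment-mass fractions of total body mass,
# each segment's mass split equally over that segment's retained markers.
# The loader renormalizes the retained-marker weights to sum to 1 (the hand
# segments carry no retained marker).

full_marker_set:
  - LFHD
  - RFHD
  - LBHD
  - RBHD
  - C7
  - T10
  - CLAV
  - STRN
  - RBAK
  - LSHO
  - LUPA
  - LELB
  - LFRM
  - LWRA
  - LWRB
  - RSHO
  - RUPA
  - RELB
  - RFRM
  - RWRA
  - RWRB
  - LASI
  - RASI
  - LPSI
  - RPSI
  - LTHI
  - LKNE
  - LTIB
  - LANK
  - LHEE
  - LTOE
  - RTHI
  - RKNE
  - RTIB
  - RANK
  - RHEE
  - RTOE

symmetric_keep:
  - LFHD
  - RFHD
  - LBHD
  - RBHD
  - C7
  - T10
  - CLAV
  - STRN
  - LSHO
  - LELB
  - LWRA
  - LWRB
  - RSHO
  - RELB
  - RWRA
  - RWRB
  - LASI
  - RASI
  - LPSI
  - RPSI
  - LKNE
  - LANK
  - LHEE
  - LTOE
  - RKNE
  - RANK
  - RHEE
  - RTOE

relative_segment_mass:
  # head + neck: 0.081 over 4 markers
  LFHD: 0.02025
  RFHD: 0.02025
  LBHD: 0.02025
  RBHD: 0.02025
  # trunk (incl. pelvis): 0.497 over 8 markers
  C7: 0.062125
  T10: 0.062125
  CLAV: 0.062125
  STRN: 0.062125
  LASI: 0.062125
  RASI: 0.062125
  LPSI: 0.062125
  RPSI: 0.062125
  # upper arm: 0.028 per side over 2 markers
  LSHO: 0.014
  LELB: 0.014
  RSHO: 0.014
  RELB: 0.014
  # forearm: 0.016 per side over 2 markers
  LWRA: 0.008
  LWRB: 0.008
  RWRA: 0.008
  RWRB: 0.008
  # thigh: 0.100 per side
  LKNE: 0.100
  RKNE: 0.100
  # shank: 0.0465 per side
  LANK: 0.0465
  RANK: 0.0465
  # foot: 0.0145 per side over 2 markers
  LHEE: 0.00725
  LTOE: 0.00725
  RHEE: 0.00725
  RTOE: 0.00725
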