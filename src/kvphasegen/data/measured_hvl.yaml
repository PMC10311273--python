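# Measured beam-quality table of the modelled kV imaging system:
# HVL in mm Al per tube potential, for four added-filtration settings.
# These measured values are the fit targets of the spectrum-weight
# reconstruction; the single printed uncertainty applies to every entry.
units: mm Al
uncertainty_mm: 0.2
settings:
  - label: "no filter"
    filters: []
  - label: "3 mm Al"
    filters: [["Al", 3.0]]
  - label: "0.5 mm Cu"
    filters: [["Cu", 0.5]]
  - label: "3 mm Al + 0.5 mm Cu"
    filters: [["Al", 3.0], ["Cu", 0.5]]
measured_hvl_mm:
  60: [3.0, 3.6, 5.5, 5.7]
  80: [4.0, 4.9, 7.4, 7.6]
  100: [4.7, 5.6, 8.6, 8.9]
  120: [5.6, 6.7, 9.8, 10.0]
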