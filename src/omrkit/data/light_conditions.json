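{
  "description": "Monochromatic light conditions in the OMR aquarium: peak wavelength (nm) -> photon flux density (umol m^-2 s^-1), as measured with a spectroradiometer at the testing apparatus.",
  "photon_flux_umol_m2_s": {
    "700": 17,
    "750": 14,
    "780": 10,
    "800": 11,
    "810": 10,
    "820": 9.5,
    "830": 12,
    "840": 15,
    "850": 9,
    "860": 8.6,
    "880": 19,
    "900": 23,
    "950": 43,
    "1000": 17
  }
}
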