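# Optical properties used for voxel Monte Carlo modeling of soft tissue.
# Units: mua, mus in mm^-1; g and n dimensionless; wavelengths in nm.
# Literature-derived soft-tissue rows plus reference media with defined
# scattering-to-absorption ratios chosen to share mueff ~= 0.50 mm^-1.
tissues:
  skin:
    700:  {mua: 0.048, mus: 14.3, g: 0.9, n: 1.4}
    800:  {mua: 0.043, mus: 15.9, g: 0.9, n: 1.4}
    900:  {mua: 0.033, mus: 16.8, g: 0.9, n: 1.4}
    1064: {mua: 0.020, mus: 16.8, g: 0.9, n: 1.4}
  fat:
    700:  {mua: 0.127, mus: 23.0, g: 0.9, n: 1.4}
    800:  {mua: 0.108, mus: 20.2, g: 0.9, n: 1.4}
    900:  {mua: 0.095, mus: 18.5, g: 0.9, n: 1.4}
    1064: {mua: 0.079, mus: 16.9, g: 0.9, n: 1.4}
  muscle:
    700:  {mua: 0.048, mus: 8.18, g: 0.9, n: 1.4}
    800:  {mua: 0.028, mus: 7.04, g: 0.9, n: 1.4}
    900:  {mua: 0.032, mus: 6.21, g: 0.9, n: 1.4}
    1064: {mua: 0.051, mus: 5.73, g: 0.9, n: 1.4}
reference_media:
  # scattering-to-absorption ratio 1:1000 (absorption dominant)
  mus_mua_0.001: {mua: 0.289, mus: 0.00029, g: 0.9, n: 1.4}
  # ratio 100:1 (scattering dominant)
  mus_mua_100:   {mua: 0.087, mus: 8.71,    g: 0.9, n: 1.4}
  # ratio ~500:1 (scattering dominant)
  mus_mua_500:   {mua: 0.041, mus: 20.2,    g: 0.9, n: 1.4}
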