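# Band-pass edges (Hz) of the 2AFC task stimuli, per reference condition,
# target F0 and stimulus class.  Entries marked "approximate" are read from
# the published stimulus diagrams rather than the text; edit freely — the
# synthesis engine takes whatever edges are given here.
#
# Construction rules behind the defaults:
#   * standard bands are identical across the two target F0s of a ferret
#     reference pair, so the spectral range carries no F0 information;
#   * low_harmonics keeps only harmonics estimated to be resolved for the
#     listener (F0/ERB-at-F0 rule, ferret ERB law for ferrets, human for
#     humans); high_harmonics keeps only presumptively unresolved harmonics;
#   * random-phase variants reuse the band of their sine-phase counterpart.
ferret:
  "707":                      # reference pure tone 707 Hz
    f0s: [500, 1000]
    level_db_spl: 70
    standard:
      500: [1000, 10000]
      1000: [1000, 10000]
    low_harmonics:            # approximate
      500: [500, 1000]        # harmonics 1-2 (2 resolved at 500 Hz)
      1000: [1000, 3000]      # harmonics 1-3 (3 resolved at 1 kHz)
    high_harmonics:           # approximate
      500: [1500, 10000]
      1000: [4000, 10000]
  "260":                      # reference pure tone 260 Hz
    f0s: [150, 450]
    level_db_spl: 70
    standard:                 # approximate; matched edges, integer harmonics
      150: [900, 9000]
      450: [900, 9000]
    low_harmonics:            # approximate
      150: [150, 150]         # harmonic 1 only (1 resolved at 150 Hz)
      450: [450, 900]         # harmonics 1-2
    high_harmonics:           # approximate
      150: [2700, 9000]
      450: [2700, 9000]
human:
  "200":                      # 180 vs 220 Hz targets, ~200 Hz range
    f0s: [180, 220]
    level_db_spl: 70
    standard:                 # approximate; the higher F0 has the lower edge
      180: [360, 3960]
      220: [220, 3960]
    low_harmonics:
      180: [360, 1440]        # harmonics 2-8; lower spectral edge 360 Hz
      220: [220, 1760]        # harmonics 1-8; lower spectral edge 220 Hz
    high_harmonics:           # approximate
      180: [1620, 3960]
      220: [1980, 3960]
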