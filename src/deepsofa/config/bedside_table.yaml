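# Bedside SOFA band -> in-hospital mortality probability lookup, as an ICU
# clinician would read off a published table or online calculator.
# SYNTHETIC PLACEHOLDER: the published score-to-mortality correlation table
# is not reprinted here; these monotone width-2 bands are a stand-in with
# the right shape and must be replaced with transcribed values for any
# clinical use.  Bands are inclusive and must tile 0..24.
source: "synthetic placeholder (monotone, width-2 bands)"
bands:
  - {lo: 0,  hi: 1,  mortality: 0.02}
  - {lo: 2,  hi: 3,  mortality: 0.05}
  - {lo: 4,  hi: 5,  mortality: 0.09}
  - {lo: 6,  hi: 7,  mortality: 0.16}
  - {lo: 8,  hi: 9,  mortality: 0.25}
  - {lo: 10, hi: 11, mortality: 0.40}
  - {lo: 12, hi: 13, mortality: 0.52}
  - {lo: 14, hi: 15, mortality: 0.65}
  - {lo: 16, hi: 17, mortality: 0.78}
  - {lo: 18, hi: 19, mortality: 0.87}
  - {lo: 20, hi: 24, mortality: 0.93}
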