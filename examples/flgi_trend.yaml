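# 2-arm FLGI trial (T=100 in 5 blocks of 20), both arms at rate 0.3, with a
# standard-of-care trend of overall magnitude 0.24, analysed with the
# Monte-Carlo randomisation test.
design:
  K: 1
  T: 100
  J: 5
  b: 20
params:
  p0: 0.3
D: 0.24
scenario: scenario1
policy:
  rule: FLGI
  flgi_mc_reps: 100
test:
  kind: randomisation
  rand_M: 200
  alpha: 0.05
n_rep: 200
seed: 7
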