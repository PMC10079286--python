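# Default scenario grid: every disruption evaluated per programme,
# 1:100-scale cohorts, paired against status quo under one seed.
seed: 1
scale: 0.01
programmes: [breast, bowel, cervix]
durations:
  breast: [3, 6, 12]
  bowel: [3, 6, 12]
  cervix: [6, 9, 12]
out_dir: results
formats: [tsv, json]
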