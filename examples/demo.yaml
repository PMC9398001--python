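out_dir: runs/demo
seed: 7
simulate: {kind: factor, m_snps: 12000}
ldsc: {n_blocks: 100, chisq_max: 1.0e+18}
models:
  - {kind: factor}
  - {kind: simplex}
  - {kind: simplex, drop: [6]}
  - {kind: simplex, drop: [2, 3, 4, 5, 6]}
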