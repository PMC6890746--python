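{
  "comment": "Fixed logistic surrogate combining ORF and TESTCODE features into a coding probability; deterministic stand-in for a trained coding-potential classifier, versioned so the 0.37 noncoding threshold stays meaningful.",
  "version": 1,
  "intercept": -5.0,
  "coefficients": {
    "longest_orf_nt": 0.004,
    "orf_coverage": 4.5,
    "fickett_score": 2.0
  }
}
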