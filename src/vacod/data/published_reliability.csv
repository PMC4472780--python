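reviewer,percent_agreement,kappa,ci_low,ci_high
ALL,83,0.79,0.76,0.82
1,81,0.77,0.77,0.84
2,89,0.87,0.82,0.95
3,81,0.77,0.68,0.96
4,67,0.52,0.13,0.65
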