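"""Benchmarking imputers by masking known values (amputation).

Cells of a complete matrix are deleted completely at random, re-imputed, and
scored as the proportion restored exactly.  With grouped (dependent) traits
the chained-equations imputer beats the mode baseline decisively.
"""

from nomtrait import SyntheticSpec, benchmark_imputers, generate

tm, _ = generate(SyntheticSpec(theta=0.9, seed=3))
res = benchmark_imputers(
    tm, methods=("mode", "polytomous"),
    proportions=(0.05, 0.15, 0.25), repetitions=20, seed=4,
)
cols = ["method", "proportion", "mean", "ci95_half"]
print(res.summary[cols].round(3).to_string(index=False))
print("\nmean = proportion of masked cells restored correctly over 20 replicates")
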