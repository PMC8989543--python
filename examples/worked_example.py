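"""Why testing against a baseline expectation beats case-control counting.

A region's risk alleles sit at frequency 0.01 per allele in patients and
0.001 in the unaffected; disease prevalence is 1%.  With 500 cases and
500 controls the expected allele counts are 10 vs 1 — a pooled chi-squared
comparison barely notices.  Knowing the *population* baseline (frequency
0.00109, hence 1.09 expected alleles among the cases) makes the same
observation astronomically unlikely under the null.
"""

from runner_burden import worked_example

we = worked_example()

print(f"population allele frequency : {we['population_frequency']:.5f}")
print(f"expected case alleles       : {we['expected_case_alleles']:.0f}")
print(f"expected control alleles    : {we['expected_control_alleles']:.0f}")
print(f"pooled frequency            : {we['pooled_frequency']:.4f}")
print(f"Pearson X^2 (1 df)          : {we['chi2']:.2f}")
print(f"case-control p-value        : {we['chi2_p']:.4f}")
print(f"baseline expected count     : {we['baseline_expected_count']:.2f}")
print(f"P(Y >= 10 | baseline)       : {we['nb_tail_p']:.3g}")
print(f"... with baseline tripled   : {we['nb_tail_p_tripled_baseline']:.3g}")

print()
print("The tail probability is ~4 orders of magnitude below the")
print("case-control p-value: an accurate baseline converts the same data")
print("into far stronger evidence.  A 3x-biased baseline (e.g. from an")
print("unpurified background) erodes most of that advantage.")
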