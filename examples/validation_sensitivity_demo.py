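"""Assay-validation sensitivity with a Wilson score interval.

Evaluates the variant caller against the validation truth set: 74
expected variants (18 disease-causing mutations in 13 control samples
plus 56 exonic polymorphisms), of which 72 were recovered — the misses
are a homopolymer-stretch indel and one polymorphism.
"""

from hlhpanel.cohort_stats import sensitivity_eval
from hlhpanel.datasets import validation_sets

truth, called = validation_sets()
report = sensitivity_eval(truth, called, confidence=0.95)

print(f"expected variants: {report.n_expected}")
print(f"correctly called:  {report.n_called}")
print(f"sensitivity: {100 * report.sensitivity:.1f}%")
print(f"95% Wilson CI: {100 * report.ci_low:.1f} - {100 * report.ci_high:.1f}")
# The Wilson interval inverts the score test, so it behaves sensibly
# near 100%: the upper bound stays below 1 despite only two misses.
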