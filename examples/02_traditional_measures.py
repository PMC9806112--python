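"""Run the four traditional use measures on one simulated subject.

Vector magnitude (VM) and activity counts (AC) react to how much the
wrist accelerates; the gross-movement score (GM) to how far the forearm
rotates while staying in the functional space (|pitch| < 30 deg); GMAC
requires both positive counts and a functional-space pitch. The printed
sensitivity/specificity show the over/under-estimation trade-off: counts
fire during gait (false positives), GM misses hand-dominant use (false
negatives), GMAC splits the difference.
"""

from limbuse import simulate_cohort
from limbuse.pipeline import evaluate_subjects

subjects, _ = simulate_cohort(n_subjects=2, seed=3)
df = evaluate_subjects(subjects)

summary = df.groupby("measure")[["sensitivity", "specificity", "youden"]]
print(summary.mean().round(3))
print("\nYouden = sensitivity + specificity - 1 "
      "(1 = perfect, 0 = chance).")
print("Expect: VM/AC sensitive but unspecific, GM specific but "
      "insensitive, GMAC the best traditional compromise.")
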