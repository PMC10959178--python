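"""Classify the 18-case reference cohort end to end.

Simulates the full cohort (13 ground-truth signaling IgM BCRs, 5
non-signaling) plus three non-signaling control samples, two replicate
acquisitions each, and classifies every case against the upper limit of the
control strengths.
"""

from autobcr.reference import COHORT_CASES, run_reference_cohort

result = run_reference_cohort(seed=1)

print(f"classification threshold (max control strength): {result.threshold:.4f}\n")
print(f"{'case':>8} {'isotype':>8} {'truth':>14} {'mean strength':>14}  call")
truth = {cid: (iso, sig) for cid, iso, sig in COHORT_CASES}
for cid, call in result.calls.items():
    iso, sig = truth[cid]
    label = "signaling" if sig else "non_signaling"
    print(f"{cid:>8} {iso:>8} {label:>14} {result.mean_strengths[cid]:14.4f}  {call}")

print(
    f"\n{result.n_signaling} of {len(result.calls)} cases classified as "
    "autonomously signaling (ground truth: 13). Non-signaling cases sit at "
    "the ~5% false-positive floor of the statistic and occasionally exceed "
    "the finite control maximum."
)
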