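"""Bundled reference datasets.

``screening_summary.csv`` holds the published directional outcomes of the
laboratory aphid plant-acceptance screening of the European winter wheat
and spring barley cultivar panels: per ordered (emitter, receiver)
direction, the mean (+/- SE) number of settled aphids on the exposed
receiver and on its clean-air control, and the reported p-value of the
contrast. Two rows per unordered pair (one per direction), 18 pairs total.
"""

from importlib import resources

import pandas as pd

from ..screening import classify_pair, directional_test_from_summary, PairClassification


def load_screening_summary() -> pd.DataFrame:
    """Published directional screening outcomes for the cultivar panels."""
    with resources.files(__package__).joinpath("screening_summary.csv").open() as fh:
        return pd.read_csv(fh)


def classify_screening_summary(alpha: float = 0.05) -> list[PairClassification]:
    """Apply the pair-classification rule to the published directional
    outcomes (unadjusted p-values, reduction = lower mean on the exposed
    receiver than on its control)."""
    df = load_screening_summary()
    tests = {}
    for rec in df.itertuples(index=False):
        tests[(rec.emitter, rec.receiver)] = directional_test_from_summary(
            rec.emitter, rec.receiver, rec.mean_exposed, rec.mean_control,
            rec.p_value, alpha=alpha)
    out = []
    for (e, r), t in sorted(tests.items()):
        if e < r and (r, e) in tests:
            out.append(classify_pair(t, tests[(r, e)]))
    return out
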