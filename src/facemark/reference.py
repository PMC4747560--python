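"""Published reference results shipped with the package.

``load_recognition_rates`` returns the per-emotion recognition rates
reported by the original marker-placement study for every combination
of feature mode (MD/CMD), classifier (KNN/PNN), normalization scheme
and statistic.  ``published_summary_rows`` recomputes the Average and
Std Dev summary rows from those per-emotion cells with the package's
own table arithmetic, which is how the summary logic is validated
without access to the study's recordings.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .classify import summarize_rates


def load_recognition_rates() -> pd.DataFrame:
    """Long-form reference rates: mode, classifier, normalization,
    statistic, sigma (PNN spread, where applicable), emotion,
    rate_percent."""
    with resources.files("facemark.data").joinpath(
        "reference_recognition_rates.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def published_summary_rows() -> dict[tuple[str, str, str, str], dict]:
    """Average/Std-Dev rows recomputed from the reference per-emotion
    rates, keyed by (mode, classifier, normalization, statistic)."""
    df = load_recognition_rates()
    out: dict[tuple[str, str, str, str], dict] = {}
    keys = ["mode", "classifier", "normalization", "statistic"]
    for key, sub in df.groupby(keys):
        if len(sub) != 6:
            raise ValueError(f"expected 6 emotion rows for {key}, got {len(sub)}")
        mean, std = summarize_rates(sub["rate_percent"].to_numpy())
        out[tuple(key)] = {
            "average": mean,
            "std_dev": std,
            "rates": dict(zip(sub["emotion"], sub["rate_percent"])),
        }
    return out
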