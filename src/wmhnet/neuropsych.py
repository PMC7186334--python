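"""Neuropsychological composites and cognitive-impairment classification.

Raw test scores are z-scored against a reference sample and averaged into
domain composites. Timed tests (Trail Making, Stroop) are negated before
averaging so that higher always means better. Cognitive impairment is
defined by education-adjusted MoCA cut-offs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: domain -> list of (test name, reversed) pairs; reversed = timed, larger worse
DEFAULT_DOMAINS: dict[str, list[tuple[str, bool]]] = {
    "executive": [("TMT-B", True), ("Stroop C", True)],
    "processing_speed": [("TMT-A", True), ("Stroop A", True),
                         ("Stroop B", True)],
    "memory": [("VR-DR", False), ("AVLT-DDR", False)],
    "visuospatial": [("CDT", False), ("VR-C", False)],
    "language": [("CVF", False), ("BNT", False)],
}


class UnclassifiableError(ValueError):
    """MoCA classification undefined for the given education level."""


def classify_moca(moca: float, education: float) -> str:
    """Education-adjusted cognitive-impairment call from a MoCA score.

    Cut-offs: <= 19 for 1-6 years of education, <= 24 for 7-12 years,
    < 26 for more than 12 years. Returns ``"CI"`` or ``"no-CI"``.
    """
    if not 0 <= moca <= 30:
        raise ValueError("MoCA score must lie in [0, 30]")
    if education < 0:
        raise ValueError("education years must be non-negative")
    if education < 1:
        raise UnclassifiableError(
            "no cut-off is defined below 1 year of education")
    if education <= 6:
        impaired = moca <= 19
    elif education <= 12:
        impaired = moca <= 24
    else:
        impaired = moca < 26
    return "CI" if impaired else "no-CI"


def log_wmh(volume_ml, base: int = 10):
    """Log-transform a lesion volume (base 10 by default, 'Lg' columns)."""
    v = np.asarray(volume_ml, dtype=float)
    if np.any(v <= 0):
        raise ValueError("WMH volume must be positive")
    out = np.log10(v) if base == 10 else np.log(v)
    return float(out) if out.ndim == 0 else out


def zscore_composites(raw_scores: pd.DataFrame,
                      domains: dict[str, list[tuple[str, bool]]] | None = None,
                      reference_mask: pd.Series | None = None) -> pd.DataFrame:
    """Z-scored tests and domain composites.

    Each test is standardized against the reference sample (all rows by
    default; pass a boolean mask to use e.g. the control group only).
    Reversed tests contribute their negated z-score; a domain composite
    is the mean of its members' (signed) z-scores. Output columns are
    ``z_<test>`` plus one column per domain.
    """
    if domains is None:
        domains = DEFAULT_DOMAINS
    ref = raw_scores if reference_mask is None else raw_scores[reference_mask]
    out = pd.DataFrame(index=raw_scores.index)
    tests = {t for members in domains.values() for t, _ in members}
    for test in sorted(tests):
        if test not in raw_scores.columns:
            raise KeyError(f"raw-score table lacks test column {test!r}")
        col = ref[test].dropna()
        if col.size < 2:
            raise ValueError(f"test {test!r} needs >= 2 reference values")
        sd = col.std(ddof=1)
        if sd == 0:
            raise ValueError(f"test {test!r} has zero variance in reference")
        out[f"z_{test}"] = (raw_scores[test] - col.mean()) / sd
    for domain, members in domains.items():
        signed = [(-1 if rev else 1) * out[f"z_{t}"] for t, rev in members]
        out[domain] = pd.concat(signed, axis=1).mean(axis=1)
    return out
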