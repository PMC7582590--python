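"""Regulatory-mode classification from paired mRNA / RPF DE results.

A gene significantly changed at both the mRNA and RPF levels in the same
direction is *homodirectional*; in opposite directions, *opposite*;
mRNA-only changes are *transcriptional* (post-transcriptional buffering of
translation); RPF-only changes are *translational*; genes significant at
neither level are *stable*.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import MODES


def _sign(x: float) -> int:
    # zero log2FC with a significance flag is treated as positive and flagged
    return 1 if x >= 0 else -1


def classify_modes(mrna_de: pd.DataFrame, rpf_de: pd.DataFrame) -> pd.DataFrame:
    """Classify every gene present in both DE tables.

    Inputs need columns ``log2fc`` and ``significant``.  Returns a frame
    with the mode label, both fold changes and significance flags, plus a
    ``zero_sign_flag`` marking genes classified through the zero-sign rule.
    """
    genes = mrna_de.index.intersection(rpf_de.index)
    m = mrna_de.loc[genes]
    r = rpf_de.loc[genes]
    m_sig = m["significant"].to_numpy(dtype=bool)
    r_sig = r["significant"].to_numpy(dtype=bool)
    m_fc = m["log2fc"].to_numpy(dtype=float)
    r_fc = r["log2fc"].to_numpy(dtype=float)

    same_sign = np.array([_sign(a) == _sign(b) for a, b in zip(m_fc, r_fc)])
    mode = np.select(
        [m_sig & r_sig & same_sign,
         m_sig & r_sig & ~same_sign,
         m_sig & ~r_sig,
         ~m_sig & r_sig],
        ["homodirectional", "opposite", "transcriptional", "translational"],
        default="stable")
    zero_flag = ((m_sig & (m_fc == 0)) | (r_sig & (r_fc == 0)))
    return pd.DataFrame({
        "mode": mode,
        "mrna_log2fc": m_fc,
        "rpf_log2fc": r_fc,
        "mrna_significant": m_sig,
        "rpf_significant": r_sig,
        "zero_sign_flag": zero_flag,
    }, index=genes)


def buffering_summary(modes: pd.DataFrame) -> dict:
    """Mode counts/fractions and the transcriptional:translational ratio.

    The ratio quantifies post-transcriptional buffering (mRNA-only versus
    RPF-only regulation); it is ``None`` when no gene is translational.
    """
    if len(modes) == 0:
        raise ValueError("empty mode table")
    counts = {m: int((modes["mode"] == m).sum()) for m in MODES}
    n = len(modes)
    ratio = (counts["transcriptional"] / counts["translational"]
             if counts["translational"] else None)
    return {
        "n_genes": n,
        "counts": counts,
        "fractions": {m: c / n for m, c in counts.items()},
        "transcriptional_translational_ratio": ratio,
    }


def persistent_sets(sig_by_timepoint: dict[str, pd.Series]) -> dict:
    """Venn-style overlap of significant gene sets across time points."""
    sets = {tp: set(s.index[s.astype(bool)])
            for tp, s in sig_by_timepoint.items()}
    union = set().union(*sets.values()) if sets else set()
    shared = set.intersection(*sets.values()) if sets else set()
    out = {"union": len(union), "shared": len(shared)}
    for tp, s in sets.items():
        others = set().union(*(v for k, v in sets.items() if k != tp))
        out[f"{tp}_only"] = len(s - others)
    return out
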