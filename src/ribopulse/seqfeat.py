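"""Per-region mRNA sequence features and fold-change stratification.

Features per gene and region (5'UTR / CDS / 3'UTR): length, GC fraction,
length-normalized minimum free energy (NMFE) from a Nussinov-style pairing
dynamic program, and G-quadruplex region counts from a G4Hunter-style run
score.  Per gene: upstream-AUG count (5'UTR) and rare-codon frequency
(CDS).  Genes are binned into feature quartiles and the mRNA/RPF/TE log2
fold-change distributions across quartiles are compared with a
Kruskal-Wallis test.

The folding model minimizes a sum of base-pair energies (GC -3, AU -2,
GU -1, hairpin loops of at least 3 unpaired bases, no pseudoknots); it is
deliberately simple enough to verify against exhaustive structure
enumeration.  Externally computed MFE values (e.g. from a thermodynamic
folder) can be supplied to :func:`compute_features` instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import Transcript

PAIR_ENERGY = {("G", "C"): -3.0, ("C", "G"): -3.0,
               ("A", "T"): -2.0, ("T", "A"): -2.0,
               ("G", "T"): -1.0, ("T", "G"): -1.0}
MIN_LOOP = 3  # minimum unpaired bases enclosed by a pair

DEFAULT_G4_WINDOW = 25
DEFAULT_G4_THRESHOLD = 1.2

DEFAULT_MAX_FOLD_LENGTH = 400
"""compute_features folds regions up to this length by default; longer
regions get NA unless MFE values are supplied externally."""

try:  # optional JIT for the O(n^3) folding DP
    from numba import njit as _njit
except Exception:  # pragma: no cover - numba present in the supported env
    _njit = None


# ---------------------------------------------------------------------------
# Minimum free energy (Nussinov-style energy DP)


def _pair_energy_matrix(seq: str) -> np.ndarray:
    code = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
    for pos, ch in enumerate(seq):
        if ch not in code:
            raise ValueError(f"non-ACGT(U) symbol {ch!r} at position {pos}")
    x = np.array([code[c] for c in seq], dtype=np.int8)
    e = np.zeros((4, 4))
    e[2, 1] = e[1, 2] = -3.0
    e[0, 3] = e[3, 0] = -2.0
    e[2, 3] = e[3, 2] = -1.0
    return e[x[:, None], x[None, :]]


def _fold_python(pair: np.ndarray) -> float:
    n = pair.shape[0]
    e = np.zeros((n, n))
    for d in range(MIN_LOOP + 1, n):
        for i in range(n - d):
            j = i + d
            best = min(e[i + 1, j], e[i, j - 1])
            if pair[i, j] < 0:
                best = min(best, e[i + 1, j - 1] + pair[i, j])
            for k in range(i + 1, j):
                val = e[i, k] + e[k + 1, j]
                if val < best:
                    best = val
            e[i, j] = best
    return float(e[0, n - 1])


if _njit is not None:
    _fold_jit = _njit(cache=True)(_fold_python)
else:
    _fold_jit = _fold_python


def fold_energy(sequence: str) -> tuple[float, float]:
    """Minimum free energy of the best pseudoknot-free pairing and NMFE.

    Returns ``(mfe, mfe / length)``; both are <= 0.  Deterministic.
    """
    if len(sequence) < 1:
        raise ValueError("sequence must have length >= 1")
    seq = sequence.upper()
    pair = _pair_energy_matrix(seq)
    if len(seq) <= MIN_LOOP + 1:
        return 0.0, 0.0
    mfe = float(_fold_jit(pair))
    return mfe, mfe / len(seq)


# ---------------------------------------------------------------------------
# G-quadruplex run scoring


def g4_scores(sequence: str) -> np.ndarray:
    """Per-base run score: +min(run, 4) in G runs, -min(run, 4) in C runs."""
    seq = sequence.upper()
    scores = np.zeros(len(seq))
    i = 0
    while i < len(seq):
        ch = seq[i]
        j = i
        while j < len(seq) and seq[j] == ch:
            j += 1
        if ch == "G":
            scores[i:j] = min(j - i, 4)
        elif ch == "C":
            scores[i:j] = -min(j - i, 4)
        i = j
    return scores


def g4_count(sequence: str, window: int = DEFAULT_G4_WINDOW,
             threshold: float = DEFAULT_G4_THRESHOLD) -> int:
    """Number of merged windows whose mean run score reaches the threshold."""
    if window < 10:
        raise ValueError("window must be >= 10")
    scores = g4_scores(sequence)
    if len(scores) == 0:
        return 0
    if len(scores) <= window:
        return int(scores.mean() >= threshold)
    kernel = np.convolve(scores, np.ones(window) / window, mode="valid")
    positive = kernel >= threshold
    # merge overlapping positive windows into counted regions
    starts = np.flatnonzero(positive)
    if starts.size == 0:
        return 0
    breaks = np.flatnonzero(np.diff(starts) >= window)
    return int(breaks.size + 1)


# ---------------------------------------------------------------------------
# Rare codons


def load_codon_usage() -> pd.Series:
    """Human codon usage (occurrences per thousand codons), shipped as data."""
    path = resources.files("ribopulse.data") / "human_codon_usage.tsv"
    table = pd.read_csv(path, sep="\t")
    return table.set_index("codon")["per_thousand"]


def rare_codon_set(usage: pd.Series | None = None,
                   quantile: float = 0.10) -> frozenset[str]:
    """Bottom-decile sense codons of the usage table (stop codons excluded)."""
    usage = load_codon_usage() if usage is None else usage
    sense = usage.drop(index=["TAA", "TAG", "TGA"], errors="ignore")
    k = max(1, int(len(sense) * quantile))
    return frozenset(sense.nsmallest(k).index)


def rare_codon_frequency(cds: str, rare: frozenset[str]) -> float:
    codons = [cds[i:i + 3] for i in range(0, len(cds) - 2, 3)]
    return sum(c in rare for c in codons) / len(codons)


# ---------------------------------------------------------------------------
# Feature table


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def count_uaug(utr5: str) -> int:
    """Overlapping ATG occurrences upstream of the annotated start."""
    n, start = 0, 0
    while True:
        i = utr5.find("ATG", start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def compute_features(transcripts: list[Transcript],
                     rare_codons: frozenset[str] | None = None,
                     compute_mfe: bool = True,
                     max_fold_length: int = DEFAULT_MAX_FOLD_LENGTH,
                     external_mfe: pd.DataFrame | None = None,
                     g4_window: int = DEFAULT_G4_WINDOW,
                     g4_threshold: float = DEFAULT_G4_THRESHOLD) -> pd.DataFrame:
    """Per-gene feature table with ``region_feature`` columns.

    Columns: ``{utr5,cds,utr3}_{length,gc,nmfe,g4}`` plus ``uaug_count``
    and ``rcf``.  Absent regions yield NA (not 0).  ``external_mfe`` may
    provide precomputed MFE values (genes x regions, columns named
    ``utr5``/``cds``/``utr3``); regions longer than ``max_fold_length``
    are otherwise left NA rather than folded.
    """
    rare = rare_codon_set() if rare_codons is None else rare_codons
    rows = []
    for t in transcripts:
        row: dict[str, float] = {"gene_id": t.gene_id}
        for region in ("utr5", "cds", "utr3"):
            seq = getattr(t, region)
            if not seq:
                row[f"{region}_length"] = np.nan
                row[f"{region}_gc"] = np.nan
                row[f"{region}_nmfe"] = np.nan
                row[f"{region}_g4"] = np.nan
                continue
            row[f"{region}_length"] = len(seq)
            row[f"{region}_gc"] = gc_fraction(seq)
            if external_mfe is not None and region in external_mfe.columns \
                    and t.gene_id in external_mfe.index \
                    and not pd.isna(external_mfe.loc[t.gene_id, region]):
                row[f"{region}_nmfe"] = (
                    float(external_mfe.loc[t.gene_id, region]) / len(seq))
            elif compute_mfe and len(seq) <= max_fold_length:
                row[f"{region}_nmfe"] = fold_energy(seq)[1]
            else:
                row[f"{region}_nmfe"] = np.nan
            row[f"{region}_g4"] = g4_count(seq, g4_window, g4_threshold)
        row["uaug_count"] = count_uaug(t.utr5) if t.utr5 else np.nan
        row["rcf"] = rare_codon_frequency(t.cds, rare)
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# Quartile stratification + Kruskal-Wallis


@dataclass
class StratifiedComparison:
    feature: str
    region: str
    response: str
    quartiles: pd.Series        # 1-4 per gene
    h_statistic: float
    pvalue: float
    medians: dict[int, float]   # per-quartile response medians
    n_genes: int


def assign_quartiles(values: pd.Series) -> pd.Series:
    """Quartile labels 1-4 with edges at the 25/50/75 percentiles.

    Values equal to an edge are assigned to the lower bin.
    """
    v = values.dropna()
    edges = np.quantile(v, [0.25, 0.5, 0.75])
    if edges[0] == edges[2]:
        raise ValueError("feature is constant; quartiles undefined")
    labels = np.searchsorted(edges, v.to_numpy(), side="left") + 1
    return pd.Series(labels, index=v.index)


def stratify_and_test(features: pd.DataFrame, responses: pd.DataFrame,
                      feature: str, region: str, response: str,
                      min_genes: int = 40) -> StratifiedComparison:
    """Kruskal-Wallis comparison of a response across feature quartiles.

    ``feature`` names a feature (``length``, ``gc``, ``nmfe``, ``g4``,
    ``uaug_count``, ``rcf``); ``region`` selects the region column
    (ignored for the per-gene features).  ``response`` names a column of
    ``responses`` (e.g. ``mrna_log2fc``).
    """
    col = feature if feature in ("uaug_count", "rcf") else f"{region}_{feature}"
    if col not in features.columns:
        raise KeyError(f"unknown feature column {col!r}")
    joined = pd.concat([features[col], responses[response]], axis=1).dropna()
    if len(joined) < min_genes:
        raise ValueError(f"only {len(joined)} genes with non-NA feature and "
                         f"response; need >= {min_genes}")
    quart = assign_quartiles(joined[col])
    groups = [joined.loc[quart.index[quart == q], response].to_numpy()
              for q in (1, 2, 3, 4)]
    groups = [grp for grp in groups if len(grp)]
    h, p = stats.kruskal(*groups)
    medians = {q: float(np.median(joined.loc[quart.index[quart == q], response]))
               for q in (1, 2, 3, 4) if (quart == q).any()}
    return StratifiedComparison(feature=feature, region=region,
                                response=response, quartiles=quart,
                                h_statistic=float(h), pvalue=float(p),
                                medians=medians, n_genes=len(joined))
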