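"""miRNA seed-target analysis and tRNA-derived small RNA (tsRNA) handling.

Target identification is by direct seed matching: the reverse complement
of small-RNA nucleotides 2-8 (the seed) is counted in 3'UTR sequences,
and fold-change distributions of genes stratified by site count are
compared to the zero-site background with a two-sided two-sample
Kolmogorov-Smirnov test.

tsRNA reads are assigned to tRNA references by tiered matching (exact
substring, then Hamming distance 1-3 over all gapless offsets), then
classified by origin landmark (5' mature, 3' mature including the CCA
tail, D/anticodon loop, 5' precursor leader) and by length class
(tRF 14-30 nt, tRH 28-36 nt, with the 28-30 nt overlap resolved by
anticodon-loop overlap).  Species sharing parent amino acid, anticodon,
origin and class are merged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from . import diffexpr
from .diffexpr import CountMatrix
from .simulate import ORIGIN_SUFFIX, Transcript, count_matches, revcomp_dna

DEFAULT_BINS = ((1, 1), (2, 2), (3, None))  # site-count strata: 1, 2, >=3


def extract_seed(seq: str) -> str:
    """Nucleotides 2-8 of a small RNA (1-based), as RNA-alphabet string."""
    s = seq.upper().replace("T", "U")
    if len(s) < 8:
        raise ValueError("small RNA shorter than 8 nt has no seed")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"seed contains non-ACGU symbol: {sorted(bad)[0]}")
    return s[1:8]


def count_seed_sites(smallrnas: dict[str, str],
                     transcripts: list[Transcript]) -> pd.DataFrame:
    """Seed-match site counts per (gene, small RNA).

    A site is an occurrence (overlapping occurrences counted) of the DNA
    reverse complement of the seed in the gene's 3'UTR.
    """
    sites = {}
    for sid, seq in smallrnas.items():
        target = revcomp_dna(extract_seed(seq))
        sites[sid] = [count_matches(target, t.utr3) for t in transcripts]
    return pd.DataFrame(sites, index=[t.gene_id for t in transcripts],
                        dtype=np.int64)


# ---------------------------------------------------------------------------
# Site-count-stratified CDF analysis


@dataclass
class TargetCDFResult:
    stratum: str
    n_genes: int
    n_background: int
    ks_statistic: float
    pvalue: float
    median_shift: float  # median(stratum response) - median(background)


def target_cdf_test(site_counts: pd.Series, response: pd.Series,
                    bins=DEFAULT_BINS, min_genes: int = 20
                    ) -> list[TargetCDFResult]:
    """KS comparison of response CDFs per site-count stratum vs background.

    ``site_counts`` holds (possibly pooled over a small-RNA set) 3'UTR
    site counts per gene; the background is the genes with zero sites.
    Bins are (lo, hi) pairs with ``hi=None`` meaning unbounded; strata
    with fewer than ``min_genes`` genes are skipped with a notice entry.
    """
    joined = pd.concat([site_counts.rename("sites"),
                        response.rename("response")], axis=1).dropna()
    background = joined.loc[joined["sites"] == 0, "response"].to_numpy()
    if len(background) == 0:
        raise ValueError("no zero-site background genes")
    results = []
    for lo, hi in bins:
        label = f">={lo}" if hi is None else (str(lo) if lo == hi
                                              else f"{lo}-{hi}")
        mask = joined["sites"] >= lo
        if hi is not None:
            mask &= joined["sites"] <= hi
        values = joined.loc[mask, "response"].to_numpy()
        if len(values) < min_genes:
            results.append(TargetCDFResult(label, len(values),
                                           len(background), np.nan, np.nan,
                                           np.nan))
            continue
        ks = stats.ks_2samp(values, background, alternative="two-sided")
        results.append(TargetCDFResult(
            stratum=label, n_genes=len(values), n_background=len(background),
            ks_statistic=float(ks.statistic), pvalue=float(ks.pvalue),
            median_shift=float(np.median(values) - np.median(background))))
    return results


# ---------------------------------------------------------------------------
# tsRNA mapping and classification

TRF_RANGE = (14, 30)
TRH_RANGE = (28, 36)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, 9) for c in seq.upper()], dtype=np.int8)


def classify_length(length: int, start: int, end: int,
                    landmarks: pd.Series) -> str | None:
    """tRF / tRH call from read length, with the 28-30 nt overlap zone
    resolved by anticodon-loop overlap (precursor coordinates)."""
    if length < TRF_RANGE[0] or length > TRH_RANGE[1]:
        return None
    if length > TRF_RANGE[1]:
        return "tRH"
    if length < TRH_RANGE[0]:
        return "tRF"
    overlaps_acloop = (start < landmarks["acloop_end"]
                       and end > landmarks["acloop_start"])
    return "tRH" if overlaps_acloop else "tRF"


def classify_origin(start: int, end: int, landmarks: pd.Series) -> str | None:
    """Origin landmark call for a read at [start, end) on the precursor."""
    if start == landmarks["mature_start"]:
        return "5p_mature"
    if end == landmarks["mature_end"]:  # CCA-tailed 3' terminus
        return "3p_mature"
    if end <= landmarks["leader_len"]:
        return "5p_precursor"
    touches_dloop = (start < landmarks["dloop_end"]
                     and end > landmarks["dloop_start"])
    touches_acloop = (start < landmarks["acloop_end"]
                      and end > landmarks["acloop_start"])
    inside_mature = (start > landmarks["mature_start"]
                     and end < landmarks["mature_end"])
    if inside_mature and (touches_dloop or touches_acloop):
        return "da_loop"
    return None


def map_tsrna(reads: pd.DataFrame | list[str], refs: dict[str, str],
              landmarks: pd.DataFrame, max_mismatches: int = 3
              ) -> tuple[pd.DataFrame, int]:
    """Assign small-RNA reads to tRNA references and classify them.

    Reads may be a list of sequences or a frame with columns ``read_id``
    and ``seq``.  Matching is tiered: exact substring first, then Hamming
    distance 1..``max_mismatches`` scanning every gapless offset
    (deletions are approximated by this offset scan).  Each read gets its
    tier-best reference; reads matching nothing, or whose best placement
    fits no origin/length class, land in the unassigned bucket.

    Returns ``(annotations, n_unassigned)``.
    """
    missing = set(refs) - set(landmarks.index)
    if missing:
        raise ValueError(f"landmark table missing tRNA: {sorted(missing)[0]}")
    if isinstance(reads, pd.DataFrame):
        read_ids = list(reads["read_id"])
        seqs = list(reads["seq"])
    else:
        read_ids = [f"read{i}" for i in range(len(reads))]
        seqs = list(reads)
    seqs = [s.upper().replace("U", "T") for s in seqs]

    enc_refs = {rid: _encode(s) for rid, s in refs.items()}
    rows = []
    n_unassigned = 0
    for rid_read, seq in zip(read_ids, seqs):
        # candidate placements at the best (lowest-mismatch) tier
        candidates: list[tuple[str, int]] = []
        tier = None
        for ref_id, ref_seq in refs.items():
            pos = ref_seq.find(seq)
            while pos >= 0:
                candidates.append((ref_id, pos))
                pos = ref_seq.find(seq, pos + 1)
        if candidates:
            tier = 0
        elif max_mismatches > 0:
            enc = _encode(seq)
            hits: list[tuple[int, str, int]] = []
            for ref_id, ref_enc in enc_refs.items():
                if len(ref_enc) < len(enc):
                    continue
                windows = sliding_window_view(ref_enc, len(enc))
                mm = (windows != enc).sum(axis=1)
                good = np.flatnonzero(mm <= max_mismatches)
                hits.extend((int(mm[k]), ref_id, int(k)) for k in good)
            if hits:
                tier = min(h[0] for h in hits)
                candidates = [(r, k) for m, r, k in hits if m == tier]
        if tier is None:
            n_unassigned += 1
            continue
        # among equal-tier placements, prefer one consistent with a
        # cleavage landmark (valid origin and length class)
        chosen = None
        for ref_id, start in candidates:
            lm = landmarks.loc[ref_id]
            end = start + len(seq)
            origin = classify_origin(start, end, lm)
            cls = classify_length(len(seq), start, end, lm)
            if origin is not None and cls is not None:
                chosen = (ref_id, start, lm, origin, cls)
                break
        if chosen is None:
            n_unassigned += 1
            continue
        ref_id, start, lm, origin, cls = chosen
        rows.append({
            "read_id": rid_read, "ref_id": ref_id, "aa": lm["aa"],
            "anticodon": lm["anticodon"], "origin": origin, "cls": cls,
            "start": start, "length": len(seq), "tier": tier,
        })
    return pd.DataFrame(rows), n_unassigned


def merged_species_id(aa: str, anticodon: str, cls: str, origin: str) -> str:
    return f"{aa}{anticodon}-{cls}-{ORIGIN_SUFFIX[origin]}"


def merge_species(annotations: pd.DataFrame) -> pd.DataFrame:
    """Sum counts over (amino acid, anticodon, origin, class) species.

    Numeric columns other than coordinates are summed; if none are
    present each annotation row contributes a count of 1.  The result is
    indexed by the merged species id ``<AA><anticodon>-<class>-<suffix>``.
    """
    keys = ["aa", "anticodon", "cls", "origin"]
    drop = {"start", "length", "tier"}
    numeric = [c for c in annotations.columns
               if c not in keys and c not in drop
               and pd.api.types.is_numeric_dtype(annotations[c])]
    work = annotations.copy()
    if not numeric:
        work["count"] = 1
        numeric = ["count"]
    merged = work.groupby(keys, sort=True)[numeric].sum()
    merged.index = [merged_species_id(aa, ac, cls, origin)
                    for aa, ac, cls, origin in merged.index]
    merged.index.name = "species"
    return merged


# ---------------------------------------------------------------------------
# tsRNA differential expression


def robust_expression_filter(counts: CountMatrix,
                             cpm_threshold: float = 100.0) -> CountMatrix:
    """Keep species with CPM above threshold in every sample of at least
    one condition (the robust-expression rule)."""
    c = diffexpr.cpm(counts)
    keep = pd.Series(False, index=counts.counts.index)
    for cond in dict.fromkeys(counts.samples["condition"]):
        ss = counts.samples_for(condition=cond)
        keep |= (c[ss] > cpm_threshold).all(axis=1)
    return CountMatrix(counts.counts.loc[keep].copy(), counts.samples.copy())


def tsrna_de(merged_counts: CountMatrix, treated: str, control: str,
             cpm_threshold: float = 100.0,
             alpha: float = diffexpr.DEFAULT_ALPHA,
             lfc_threshold: float = diffexpr.DEFAULT_LFC_THRESHOLD
             ) -> pd.DataFrame:
    """Robust-expression filter followed by the NB exact-test path."""
    filtered = robust_expression_filter(merged_counts, cpm_threshold)
    group_a = filtered.samples_for(condition=treated)
    group_b = filtered.samples_for(condition=control)
    sub = filtered.subset(group_a + group_b)
    factors = diffexpr.tmm_factors(sub)
    phi, _ = diffexpr.estimate_dispersion(sub, factors=factors)
    return diffexpr.exact_test(sub, group_a, group_b, phi, factors,
                               alpha=alpha, lfc_threshold=lfc_threshold)
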