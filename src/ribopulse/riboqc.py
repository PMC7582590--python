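"""Ribosome-profiling quality control.

Feature mapping rates, metagene density profiles around CDS start/stop
codons, per-read-length P-site offset calibration by start-codon
cross-correlation, and sub-codon phasing (triplet periodicity).

Reads are tables with columns ``gene_id``, ``pos5`` (0-based transcript
coordinate of the read 5' end) and ``length``.  RPF reads are anchored by
their P-site (``pos5 + offset``); mRNA reads, which have no biological
P-site, are anchored by their 5' end (offset 0).  Frames are 0-based:
frame 0 is the annotated reading frame (the "first canonical frame").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import Transcript

REGIONS = ("utr5", "cds", "utr3")


@dataclass
class MetageneProfile:
    anchor: str                 # "start" or "stop"
    window: tuple[int, int]     # half-open, relative to anchor
    positions: np.ndarray
    density: np.ndarray         # mean normalized density per position
    n_transcripts: int


@dataclass
class PsiteCalibration:
    per_length: pd.DataFrame    # index read length: offset, sharpness, n_reads
    consensus: int


@dataclass
class PhasingSummary:
    counts: np.ndarray          # reads per frame 0/1/2
    fractions: np.ndarray

    def __post_init__(self) -> None:
        assert abs(self.fractions.sum() - 1.0) < 1e-12


def _transcript_arrays(transcripts: list[Transcript]):
    idx = {t.gene_id: i for i, t in enumerate(transcripts)}
    cds_start = np.array([t.cds_start for t in transcripts])
    cds_end = np.array([t.cds_end for t in transcripts])
    length = np.array([t.length for t in transcripts])
    return idx, cds_start, cds_end, length


def _gene_indices(reads: pd.DataFrame, idx: dict[str, int]) -> np.ndarray:
    try:
        return reads["gene_id"].map(idx).to_numpy(dtype=np.int64)
    except Exception as err:
        missing = reads.loc[~reads["gene_id"].isin(idx), "gene_id"]
        raise ValueError(f"unknown gene in reads: {missing.iloc[0]}") from err


def _validate_bounds(reads: pd.DataFrame, g: np.ndarray,
                     length: np.ndarray) -> None:
    pos5 = reads["pos5"].to_numpy()
    end = pos5 + reads["length"].to_numpy()
    bad = np.flatnonzero((pos5 < 0) | (end > length[g]))
    if bad.size:
        raise ValueError(f"read {bad[0]} lies outside its transcript")


def feature_mapping_rates(reads: pd.DataFrame,
                          transcripts: list[Transcript],
                          offset: int = 0) -> dict[str, float]:
    """Fraction of reads whose anchor falls in each transcript region.

    Pass the calibrated P-site offset for RPF reads and 0 (the default)
    for mRNA reads.  Fractions over 5'UTR/CDS/3'UTR sum to 1.
    """
    if len(reads) == 0:
        raise ValueError("empty read list")
    idx, cds_start, cds_end, length = _transcript_arrays(transcripts)
    g = _gene_indices(reads, idx)
    _validate_bounds(reads, g, length)
    anchor = reads["pos5"].to_numpy() + offset
    n = len(reads)
    in_utr5 = anchor < cds_start[g]
    in_cds = (anchor >= cds_start[g]) & (anchor < cds_end[g])
    return {
        "utr5": float(in_utr5.sum()) / n,
        "cds": float(in_cds.sum()) / n,
        "utr3": float((~in_utr5 & ~in_cds).sum()) / n,
    }


def metagene(reads: pd.DataFrame, transcripts: list[Transcript],
             anchor: str = "start", window: tuple[int, int] = (-30, 60),
             offset: int = 0) -> MetageneProfile:
    """Mean normalized anchor-relative read density.

    Per transcript, positional counts over the window are divided by that
    transcript's mean count across the window (transcripts with zero mean
    are skipped), then averaged across transcripts.  Only transcripts that
    fully contain the window are used.
    """
    if anchor not in ("start", "stop"):
        raise ValueError("anchor must be 'start' or 'stop'")
    lo, hi = window
    if not lo <= 0 < hi:
        raise ValueError("window must contain the anchor position")
    idx, cds_start, cds_end, length = _transcript_arrays(transcripts)
    g = _gene_indices(reads, idx)
    _validate_bounds(reads, g, length)
    anchor_pos = cds_start if anchor == "start" else cds_end
    eligible = (anchor_pos + lo >= 0) & (anchor_pos + hi <= length)

    rel = reads["pos5"].to_numpy() + offset - anchor_pos[g]
    keep = eligible[g] & (rel >= lo) & (rel < hi)
    width = hi - lo
    counts = np.zeros((len(transcripts), width))
    np.add.at(counts, (g[keep], rel[keep] - lo), 1.0)

    used = eligible & (counts.sum(axis=1) > 0)
    if not used.any():
        raise ValueError("no eligible transcripts for metagene profile")
    norm = counts[used] / counts[used].mean(axis=1, keepdims=True)
    return MetageneProfile(anchor=anchor, window=(lo, hi),
                           positions=np.arange(lo, hi),
                           density=norm.mean(axis=0),
                           n_transcripts=int(used.sum()))


def calibrate_psite(reads: pd.DataFrame, transcripts: list[Transcript],
                    candidate_offsets: range | list[int] = range(0, 18),
                    min_reads: int = 100) -> PsiteCalibration:
    """Per-read-length P-site offsets by start-codon cross-correlation.

    For each read length with at least ``min_reads`` reads, the chosen
    offset maximizes the number of reads with ``pos5 + offset`` exactly on
    a CDS start codon; ties go to the smaller offset.  The sharpness score
    is the winning count divided by the summed counts over all candidate
    offsets.  The consensus is the read-count-weighted mode of the
    per-length offsets.
    """
    idx, cds_start, cds_end, length = _transcript_arrays(transcripts)
    g = _gene_indices(reads, idx)
    _validate_bounds(reads, g, length)
    pos5 = reads["pos5"].to_numpy()
    rlen = reads["length"].to_numpy()
    rows = {}
    for l in np.unique(rlen):
        mask = rlen == l
        if mask.sum() < min_reads:
            continue
        cands = [o for o in candidate_offsets if 0 <= o < l]
        scores = np.array([
            int((pos5[mask] + o == cds_start[g[mask]]).sum()) for o in cands])
        if scores.sum() == 0:
            continue
        best = int(np.argmax(scores))  # argmax takes the first (smallest) tie
        rows[int(l)] = {"offset": cands[best],
                        "sharpness": scores[best] / scores.sum(),
                        "n_reads": int(mask.sum())}
    if not rows:
        raise ValueError(
            "no candidate offset has start-codon support for any read length; "
            "widen candidate_offsets or lower min_reads")
    per_length = pd.DataFrame(rows).T.astype(
        {"offset": int, "n_reads": int})
    per_length.index.name = "length"
    weight = per_length.groupby("offset")["n_reads"].sum()
    consensus = int(weight.index[np.lexsort((weight.index, -weight.values))][0])
    return PsiteCalibration(per_length=per_length, consensus=consensus)


def phasing(reads: pd.DataFrame, transcripts: list[Transcript],
            calibration: PsiteCalibration | int) -> PhasingSummary:
    """Distribution of in-CDS P-sites over the three codon positions."""
    idx, cds_start, cds_end, length = _transcript_arrays(transcripts)
    g = _gene_indices(reads, idx)
    _validate_bounds(reads, g, length)
    if isinstance(calibration, PsiteCalibration):
        offmap = calibration.per_length["offset"]
        offsets = reads["length"].map(offmap).fillna(
            calibration.consensus).to_numpy(dtype=np.int64)
    else:
        offsets = np.full(len(reads), int(calibration))
    psite = reads["pos5"].to_numpy() + offsets
    in_cds = (psite >= cds_start[g]) & (psite < cds_end[g])
    if not in_cds.any():
        raise ValueError("no P-sites inside any CDS")
    frame = (psite[in_cds] - cds_start[g[in_cds]]) % 3
    counts = np.bincount(frame, minlength=3).astype(np.int64)
    return PhasingSummary(counts=counts, fractions=counts / counts.sum())


def qc_report(reads: pd.DataFrame, transcripts: list[Transcript],
              candidate_offsets: range | list[int] = range(0, 18)) -> dict:
    """Convenience wrapper running the full QC battery on RPF reads."""
    calib = calibrate_psite(reads, transcripts, candidate_offsets)
    rates = feature_mapping_rates(reads, transcripts, calib.consensus)
    phase = phasing(reads, transcripts, calib)
    start = metagene(reads, transcripts, "start", (-30, 60), calib.consensus)
    stop = metagene(reads, transcripts, "stop", (-60, 30), calib.consensus)
    return {
        "psite_offset_consensus": calib.consensus,
        "psite_offsets_by_length":
            calib.per_length["offset"].to_dict(),
        "feature_mapping_rates": rates,
        "frame_fractions": list(phase.fractions),
        "metagene_start": list(start.density),
        "metagene_stop": list(stop.density),
    }
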