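"""Ground-truth simulator for the depolarization translatome experiment.

Generates a synthetic single-isoform transcriptome, plants per-gene
regulatory modes (matched mRNA / ribosome-footprint log2 fold changes),
draws NB count matrices over replicated conditions, emits ribosome-
protected-fragment (RPF) alignments with a fixed P-site offset and
configurable reading-frame fidelity, plants miRNA seed-match sites in
3'UTRs, and cuts tRNA-derived small RNA reads from synthetic tRNA
references at defined cloverleaf landmarks.  Every random choice a
downstream module estimates (offsets, fidelities, fold changes, site
counts, fragment origins) is recorded in a :class:`SimTruth` object.

The default experimental design mirrors a membrane-depolarization time
course: four biological replicates of an untreated control and of two
post-stimulus harvests (``0h``, immediately after stimulation, and ``2h``
after a rest phase), with each treatment contrasted against control.  The
``0h`` regulatory-mode mix is transcription-heavy and the ``2h`` mix is
translation-heavy, reproducing the qualitative buffering asymmetry between
the two time points without copying dataset-specific counts.

All sequences use the DNA alphabet; RNA/DNA conversion happens at the
small-RNA comparison boundary.  Coordinates are 0-based, half-open.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .diffexpr import CountMatrix

MODES = ("homodirectional", "opposite", "transcriptional", "translational",
         "stable")

DEFAULT_MODE_MIX_0H = {
    "transcriptional": 0.35, "translational": 0.17, "homodirectional": 0.04,
    "opposite": 0.02, "stable": 0.42,
}
DEFAULT_MODE_MIX_2H = {
    "transcriptional": 0.05, "translational": 0.25, "homodirectional": 0.06,
    "opposite": 0.02, "stable": 0.62,
}

STOP_CODONS = ("TAA", "TAG", "TGA")
_NT = np.array(list("ACGT"))

TSRNA_ORIGINS = ("5p_mature", "3p_mature", "da_loop", "5p_precursor")
ORIGIN_SUFFIX = {"5p_precursor": "1", "3p_mature": "3", "5p_mature": "5",
                 "da_loop": "DA"}

_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")


def revcomp_dna(seq: str) -> str:
    """Reverse complement, accepting RNA or DNA input, returning DNA."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class Transcript:
    """Single-isoform gene model: 5'UTR + CDS + 3'UTR concatenated."""

    gene_id: str
    utr5: str
    cds: str
    utr3: str

    def __post_init__(self) -> None:
        if len(self.cds) < 6 or len(self.cds) % 3:
            raise ValueError(f"{self.gene_id}: CDS length must be a positive "
                             "multiple of 3")
        if not self.cds.startswith("ATG") or self.cds[-3:] not in STOP_CODONS:
            raise ValueError(f"{self.gene_id}: CDS must start ATG / end stop")
        for codon in range(3, len(self.cds) - 3, 3):
            if self.cds[codon:codon + 3] in STOP_CODONS:
                raise ValueError(f"{self.gene_id}: internal in-frame stop")

    @property
    def seq(self) -> str:
        return self.utr5 + self.cds + self.utr3

    @property
    def cds_start(self) -> int:
        return len(self.utr5)

    @property
    def cds_end(self) -> int:
        return len(self.utr5) + len(self.cds)

    @property
    def length(self) -> int:
        return len(self.utr5) + len(self.cds) + len(self.utr3)


@dataclass
class SimTruth:
    """Complete record of the planted structure of a simulated experiment."""

    genes: list[str]
    baseline: pd.Series                      # relative abundance, sums to 1
    modes: dict[str, pd.DataFrame]           # contrast -> mode/log2fc table
    dispersion: float | pd.Series = 0.04
    psite_offset: int = 12
    frame_fidelity: float = 0.80
    leakage: float = 0.05
    init_peak: float = 0.08
    mirna_seqs: dict[str, str] = field(default_factory=dict)
    mirna_log2fc: dict[str, dict[str, float]] = field(default_factory=dict)
    mirna_sites: pd.DataFrame | None = None  # genes x miRNA recounted sites
    tsrna_truth: pd.DataFrame | None = None
    smallrna_log2fc: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "genes": self.genes,
            "baseline": self.baseline.to_dict(),
            "modes": {c: df.to_dict(orient="index")
                      for c, df in self.modes.items()},
            "dispersion": (self.dispersion if np.isscalar(self.dispersion)
                           else pd.Series(self.dispersion).to_dict()),
            "psite_offset": self.psite_offset,
            "frame_fidelity": self.frame_fidelity,
            "leakage": self.leakage,
            "init_peak": self.init_peak,
            "mirna_seqs": self.mirna_seqs,
            "mirna_log2fc": self.mirna_log2fc,
            "mirna_sites": (None if self.mirna_sites is None
                            else self.mirna_sites.to_dict(orient="index")),
            "tsrna_truth": (None if self.tsrna_truth is None
                            else self.tsrna_truth.to_dict(orient="records")),
            "smallrna_log2fc": self.smallrna_log2fc,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class SimConfig:
    """Study conditions for :func:`simulate_experiment`.

    Defaults encode the emulated design: 2000 genes, four replicates of
    control/0h/2h libraries of ~1e6 counts, NB dispersion 0.04 (biological
    coefficient of variation 0.2, typical of cell-line replicates), planted
    effect size 1.0 log2, P-site offset 12 nt with 80% frame fidelity and
    5% UTR leakage, and a transcription-heavy 0h / translation-heavy 2h
    regulatory-mode mix.
    """

    n_genes: int = 2000
    utr5_length: tuple[int, int] = (100, 300)
    cds_codons: tuple[int, int] = (120, 400)
    utr3_length: tuple[int, int] = (200, 800)
    gc: dict[str, float] = field(default_factory=lambda: {
        "utr5": 0.55, "cds": 0.52, "utr3": 0.45})
    n_reps: int = 4
    depth: float = 1e6
    dispersion: float = 0.04
    effect_size: float = 1.0
    mode_mix: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "0h": dict(DEFAULT_MODE_MIX_0H), "2h": dict(DEFAULT_MODE_MIX_2H)})
    abundance_sigma: float = 1.0
    psite_offset: int = 12
    frame_fidelity: float = 0.80
    leakage: float = 0.05
    init_peak: float = 0.08
    read_lengths: dict[int, float] = field(default_factory=lambda: {
        27: 0.10, 28: 0.20, 29: 0.30, 30: 0.22, 31: 0.12, 32: 0.06})
    n_rpf_reads: int = 100_000
    n_mirnas: int = 10
    mirna_site_probs: tuple[float, ...] = (0.55, 0.20, 0.15, 0.10)
    mirna_effect_per_site: float = 0.2
    mirna_log2fc: float = 1.0
    n_trnas: int = 12
    n_tsrna_reads: int = 5000
    tsrna_down_log2fc: float = -1.0
    smallrna_depth: float = 1e6

    @staticmethod
    def from_dict(d: dict) -> "SimConfig":
        cfg = SimConfig()
        for k, v in d.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown simulation option {k!r}")
            if k == "read_lengths":
                v = {int(a): float(b) for a, b in v.items()}
            setattr(cfg, k, v)
        return cfg


# ---------------------------------------------------------------------------
# Transcriptome


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_NT, size=length, p=p))


def _random_cds(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """ATG + (n_codons - 2) stop-free random codons + a stop codon."""
    internal = n_codons - 2
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codons = rng.choice(_NT, size=(internal, 3), p=p)
    joined = ["".join(c) for c in codons]
    bad = [i for i, c in enumerate(joined) if c in STOP_CODONS]
    while bad:
        redraw = rng.choice(_NT, size=(len(bad), 3), p=p)
        for j, i in enumerate(bad):
            joined[i] = "".join(redraw[j])
        bad = [i for i in bad if joined[i] in STOP_CODONS]
    stop = STOP_CODONS[rng.integers(0, 3)]
    return "ATG" + "".join(joined) + stop


def make_transcriptome(n_genes: int,
                       utr5_length: tuple[int, int] = (100, 300),
                       cds_codons: tuple[int, int] = (120, 400),
                       utr3_length: tuple[int, int] = (200, 800),
                       gc: dict[str, float] | None = None,
                       seed: int = 0) -> list[Transcript]:
    """Generate ``n_genes`` random transcripts with valid CDS structure.

    Region lengths are drawn uniformly from the inclusive ranges given;
    per-region GC targets must lie in (0.2, 0.8).  Deterministic for a
    given seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    gc = dict(gc or {"utr5": 0.55, "cds": 0.52, "utr3": 0.45})
    for region, val in gc.items():
        if not 0.2 < val < 0.8:
            raise ValueError(f"GC target for {region} must be in (0.2, 0.8)")
    for name, rng_ in (("utr5", utr5_length), ("cds_codons", cds_codons),
                       ("utr3", utr3_length)):
        if rng_[1] < rng_[0] or rng_[0] < 0 or (name == "cds_codons"
                                                and rng_[0] < 3):
            raise ValueError(f"invalid length range for {name}: {rng_}")
    rng = np.random.default_rng(seed)
    width = len(str(max(n_genes - 1, 1)))
    out = []
    for i in range(n_genes):
        u5 = rng.integers(utr5_length[0], utr5_length[1] + 1)
        nc = rng.integers(cds_codons[0], cds_codons[1] + 1)
        u3 = rng.integers(utr3_length[0], utr3_length[1] + 1)
        out.append(Transcript(
            gene_id=f"G{i:0{width}d}",
            utr5=_random_seq(rng, u5, gc["utr5"]),
            cds=_random_cds(rng, nc, gc["cds"]),
            utr3=_random_seq(rng, u3, gc["utr3"]),
        ))
    return out


# ---------------------------------------------------------------------------
# Regulatory modes

_MODE_EFFECT = {
    # mode -> (mrna multiplier, rpf multiplier) applied to s * effect_size
    "homodirectional": (1, 1),
    "opposite": (1, -1),
    "transcriptional": (1, 0),
    "translational": (0, 1),
    "stable": (0, 0),
}


def mode_effects(mode: str, sign: int, effect_size: float) -> tuple[float, float]:
    """Documented mode -> (mrna_log2fc, rpf_log2fc) map."""
    a, b = _MODE_EFFECT[mode]
    return a * sign * effect_size, b * sign * effect_size


def plant_modes(genes: list[str] | list[Transcript],
                proportions: dict[str, float],
                effect_size: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """Assign each gene a regulatory mode and the implied log2 fold changes.

    ``proportions`` must cover a subset of the five modes and sum to 1;
    effect signs are assigned 50/50 by the seeded RNG.  Returns a frame
    indexed by gene with columns ``mode``, ``mrna_log2fc``, ``rpf_log2fc``.
    """
    ids = [t.gene_id if isinstance(t, Transcript) else t for t in genes]
    for m, frac in proportions.items():
        if m not in MODES:
            raise ValueError(f"unknown mode {m!r}")
        if frac < 0:
            raise ValueError(f"negative fraction for mode {m!r}")
    if abs(sum(proportions.values()) - 1.0) > 1e-9:
        raise ValueError("mode proportions must sum to 1")
    if effect_size <= 0:
        raise ValueError("effect_size must be > 0")
    rng = np.random.default_rng(seed)
    labels = list(proportions)
    probs = np.array([proportions[m] for m in labels], dtype=float)
    probs /= probs.sum()
    assigned = rng.choice(labels, size=len(ids), p=probs)
    signs = rng.choice([-1, 1], size=len(ids))
    rows = [mode_effects(m, int(s), effect_size)
            for m, s in zip(assigned, signs)]
    return pd.DataFrame({
        "mode": assigned,
        "mrna_log2fc": [r[0] for r in rows],
        "rpf_log2fc": [r[1] for r in rows],
    }, index=pd.Index(ids, name="gene_id"))


# ---------------------------------------------------------------------------
# Counts


def _draw_nb(rng: np.random.Generator, mean: np.ndarray,
             phi: np.ndarray) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    out = np.zeros(mean.shape, dtype=np.int64)
    pois = phi <= 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        size = 1.0 / phi[~pois]
        p = size / (size + mean[~pois])
        out[~pois] = rng.negative_binomial(size, p)
    return out


def random_baseline(genes: list[str], sigma: float = 1.0,
                    seed: int = 0) -> pd.Series:
    """Log-normal relative abundances, normalized to sum to 1."""
    rng = np.random.default_rng(seed)
    w = rng.lognormal(mean=0.0, sigma=sigma, size=len(genes))
    return pd.Series(w / w.sum(), index=genes, name="baseline")


def simulate_counts(truth: SimTruth, n_reps: int = 4, depth: float = 1e6,
                    dispersion: float | pd.Series | None = None,
                    seed: int = 0) -> dict[str, CountMatrix]:
    """Draw NB count matrices per assay over control plus all contrasts.

    The expected count of gene g in a library is ``baseline_g * 2**log2fc
    * depth``; dispersion may be a scalar or per-gene series (0 gives the
    Poisson limit).  Returns ``{"mRNA": CountMatrix, "RPF": CountMatrix}``
    with columns named ``assay_condition_rep``.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    phi = truth.dispersion if dispersion is None else dispersion
    phi_vec = (np.full(len(truth.genes), float(phi)) if np.isscalar(phi)
               else pd.Series(phi).loc[truth.genes].to_numpy())
    if (phi_vec < 0).any():
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    base = truth.baseline.loc[truth.genes].to_numpy()
    conditions = ["control"] + list(truth.modes)
    out = {}
    for assay, col in (("mRNA", "mrna_log2fc"), ("RPF", "rpf_log2fc")):
        data, meta = {}, []
        for cond in conditions:
            lfc = (np.zeros(len(truth.genes)) if cond == "control"
                   else truth.modes[cond][col].loc[truth.genes].to_numpy())
            mean = base * (2.0 ** lfc) * depth
            for rep in range(1, n_reps + 1):
                name = f"{assay}_{cond}_{rep}"
                data[name] = _draw_nb(rng, mean, phi_vec)
                meta.append({"sample": name, "assay": assay,
                             "condition": cond, "replicate": str(rep)})
        counts = pd.DataFrame(data, index=pd.Index(truth.genes, name="gene_id"))
        samples = pd.DataFrame(meta).set_index("sample")
        out[assay] = CountMatrix(counts, samples)
    return out


# ---------------------------------------------------------------------------
# RPF reads


def simulate_rpf_reads(transcripts: list[Transcript],
                       expression: pd.Series | None,
                       offset: int = 12, frame_fidelity: float = 0.80,
                       read_length_dist: dict[int, float] | None = None,
                       n_reads: int = 100_000, leakage: float = 0.05,
                       init_peak: float = 0.08, seed: int = 0) -> pd.DataFrame:
    """Simulate RPF alignments as (gene_id, pos5, length) rows.

    P-sites fall inside the CDS with probability ``1 - leakage`` (the
    remainder split evenly between the UTRs), land on codon starts with
    probability ``frame_fidelity`` (else uniformly on frames 1-2), and sit
    on the first codon with extra probability ``init_peak``, emulating the
    initiation-site density peak of cycloheximide ribosome profiling.  The
    read 5' end is the P-site minus ``offset``.
    """
    if not 0 <= frame_fidelity <= 1:
        raise ValueError("frame_fidelity must be in [0, 1]")
    if offset < 0:
        raise ValueError("offset must be >= 0")
    if not 0 <= leakage <= 1:
        raise ValueError("leakage must be in [0, 1]")
    read_length_dist = read_length_dist or {
        27: 0.10, 28: 0.20, 29: 0.30, 30: 0.22, 31: 0.12, 32: 0.06}
    lengths = np.array(sorted(read_length_dist))
    if offset >= lengths.min():
        raise ValueError("offset must be smaller than the minimum read length")
    lprobs = np.array([read_length_dist[l] for l in lengths], dtype=float)
    lprobs /= lprobs.sum()

    rng = np.random.default_rng(seed)
    ids = np.array([t.gene_id for t in transcripts])
    cds_start = np.array([t.cds_start for t in transcripts])
    cds_end = np.array([t.cds_end for t in transcripts])
    n_codons = (cds_end - cds_start) // 3
    total_len = np.array([t.length for t in transcripts])
    if expression is None:
        w = np.ones(len(ids)) / len(ids)
    else:
        w = pd.Series(expression).loc[ids].to_numpy(dtype=float)
        w = w / w.sum()

    g = rng.choice(len(ids), size=n_reads, p=w)
    length = rng.choice(lengths, size=n_reads, p=lprobs)
    u = rng.random(n_reads)
    leak5 = u < leakage / 2
    leak3 = (u >= leakage / 2) & (u < leakage)
    in_cds = ~(leak5 | leak3)

    codon = np.floor(rng.random(n_reads) * n_codons[g]).astype(np.int64)
    codon[rng.random(n_reads) < init_peak] = 0
    frame = np.where(rng.random(n_reads) < frame_fidelity, 0,
                     rng.integers(1, 3, size=n_reads))
    psite = cds_start[g] + 3 * codon + frame

    if leak5.any():
        lo = np.full(leak5.sum(), offset)
        hi = cds_start[g[leak5]]
        psite[leak5] = lo + np.floor(
            rng.random(leak5.sum()) * (hi - lo)).astype(np.int64)
    if leak3.any():
        lo = cds_end[g[leak3]]
        hi = total_len[g[leak3]] - length[leak3] + offset
        psite[leak3] = lo + np.floor(
            rng.random(leak3.sum()) * np.maximum(hi - lo, 1)).astype(np.int64)

    pos5 = psite - offset
    reads = pd.DataFrame({"gene_id": ids[g], "pos5": pos5, "length": length})
    bad = (reads["pos5"] < 0) | (pos5 + length > total_len[g])
    if bad.any():  # defensive: should not happen with the default geometry
        reads = reads[~bad].reset_index(drop=True)
    return reads


# ---------------------------------------------------------------------------
# miRNA target planting


def count_matches(pattern: str, text: str) -> int:
    """Overlapping occurrences of ``pattern`` in ``text``."""
    n, start = 0, 0
    while True:
        i = text.find(pattern, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def seed_site(mirna_seq: str) -> str:
    """DNA reverse complement of small-RNA nucleotides 2-8 (the seed)."""
    seq = mirna_seq.upper().replace("U", "T")
    if len(seq) < 8:
        raise ValueError("small RNA must be at least 8 nt for seed extraction")
    return revcomp_dna(seq[1:8])


def plant_mirna_targets(transcripts: list[Transcript],
                        mirnas: dict[str, str],
                        site_count_probs: tuple[float, ...] = (0.55, 0.2, 0.15, 0.1),
                        seed: int = 0
                        ) -> tuple[list[Transcript], pd.DataFrame, pd.DataFrame]:
    """Plant miRNA seed-match sites in 3'UTRs.

    Each gene draws a site count from ``site_count_probs`` (index =
    number of sites) and a random miRNA from the catalog; the 7-nt DNA
    reverse complement of the miRNA seed overwrites the 3'UTR at
    non-overlapping random positions.  Returns the updated transcripts,
    the planted (gene x miRNA) insertion counts, and the recounted
    site-count map including pre-existing chance matches.
    """
    for mid, seq in mirnas.items():
        if len(seq) < 8:
            raise ValueError(f"miRNA {mid} shorter than 8 nt")
    rng = np.random.default_rng(seed)
    ids = list(mirnas)
    probs = np.asarray(site_count_probs, dtype=float)
    probs = probs / probs.sum()
    planted = pd.DataFrame(0, index=[t.gene_id for t in transcripts],
                           columns=ids, dtype=np.int64)
    out = []
    for t in transcripts:
        k = int(rng.choice(len(probs), p=probs))
        if k == 0:
            out.append(t)
            continue
        site_len = 7
        if len(t.utr3) < k * (site_len + 3):
            warnings.warn(f"{t.gene_id}: 3'UTR too short for {k} sites; "
                          "gene skipped", RuntimeWarning)
            out.append(t)
            continue
        mid = ids[int(rng.integers(0, len(ids)))]
        site = seed_site(mirnas[mid])
        utr3 = list(t.utr3)
        chosen: list[int] = []
        candidates = rng.permutation(len(t.utr3) - site_len + 1)
        for pos in candidates:
            if all(abs(pos - c) >= site_len for c in chosen):
                chosen.append(int(pos))
                if len(chosen) == k:
                    break
        for pos in chosen:
            utr3[pos:pos + site_len] = site
        planted.loc[t.gene_id, mid] = len(chosen)
        out.append(Transcript(t.gene_id, t.utr5, t.cds, "".join(utr3)))
    recount = pd.DataFrame(
        {mid: [count_matches(seed_site(mirnas[mid]), t.utr3) for t in out]
         for mid in ids},
        index=[t.gene_id for t in out], dtype=np.int64)
    return out, planted, recount


def random_mirnas(n: int = 10, length: int = 22, seed: int = 0) -> dict[str, str]:
    """Random RNA-alphabet miRNA catalog (ids miR-1 ... miR-n)."""
    rng = np.random.default_rng(seed)
    nt = np.array(list("ACGU"))
    return {f"miR-{i + 1}": "".join(rng.choice(nt, size=length))
            for i in range(n)}


# ---------------------------------------------------------------------------
# tRNA references and tsRNA reads

_ISOTYPES = [
    ("Glu", "TTC"), ("Leu", "TAA"), ("Leu", "CAA"), ("Ala", "AGC"),
    ("Ala", "TGC"), ("Cys", "GCA"), ("Gly", "GCC"), ("Lys", "CTT"),
    ("Asp", "GTC"), ("His", "GTG"), ("Val", "CAC"), ("Ser", "GCT"),
    ("Arg", "ACG"), ("Pro", "AGG"), ("Thr", "AGT"), ("Ile", "AAT"),
]

TRF_LENGTHS = (14, 30)
TRH_LENGTHS = (28, 36)
_AMBIGUOUS_LENGTHS = (28, 30)  # class decided by anticodon-loop overlap


def make_trna_references(n_trnas: int = 12, leader_len: int = 50,
                         mature_len: int = 73, seed: int = 0
                         ) -> tuple[dict[str, str], pd.DataFrame]:
    """Synthetic precursor tRNA references plus a cloverleaf landmark table.

    Each reference is ``leader + mature + CCA`` (the mature sequence is
    stored CCA-tailed).  Landmarks use precursor coordinates: mature span,
    D-loop span, anticodon-loop span and the leader length.
    """
    if n_trnas > len(_ISOTYPES):
        raise ValueError(f"at most {len(_ISOTYPES)} synthetic isotypes available")
    rng = np.random.default_rng(seed)
    refs, rows = {}, []
    for i in range(n_trnas):
        aa, anticodon = _ISOTYPES[i]
        ref_id = f"tRNA-{aa}-{anticodon}-{i + 1}"
        mature = _random_seq(rng, mature_len, 0.55)
        # pin the anticodon triplet at mature positions 34-36 for realism
        mature = mature[:34] + anticodon + mature[37:]
        seq = _random_seq(rng, leader_len, 0.45) + mature + "CCA"
        refs[ref_id] = seq
        rows.append({
            "ref_id": ref_id, "aa": aa, "anticodon": anticodon,
            "mature_start": leader_len,
            "mature_end": leader_len + mature_len + 3,
            "dloop_start": leader_len + 13, "dloop_end": leader_len + 22,
            "acloop_start": leader_len + 31, "acloop_end": leader_len + 39,
            "leader_len": leader_len,
        })
    return refs, pd.DataFrame(rows).set_index("ref_id")


DEFAULT_CUT_PLAN = {"3p_mature": 0.45, "5p_mature": 0.25, "da_loop": 0.20,
                    "5p_precursor": 0.10}
DEFAULT_TRH_PROB = {"5p_mature": 0.85, "3p_mature": 0.05, "da_loop": 0.0,
                    "5p_precursor": 0.0}


def simulate_tsrna_reads(refs: dict[str, str], landmarks: pd.DataFrame,
                         cut_plan: dict[str, float] | None = None,
                         trh_prob: dict[str, float] | None = None,
                         n_reads: int = 5000, seed: int = 0) -> pd.DataFrame:
    """Cut small-RNA reads from tRNA references at cloverleaf landmarks.

    ``cut_plan`` maps origin (``5p_mature``, ``3p_mature``, ``da_loop``,
    ``5p_precursor``) to the fraction of reads cut there; ``trh_prob``
    gives the probability that a read from an origin is a tRNA half
    (length 31-36 nt) rather than a fragment (14-27 nt).  Reads are exact
    substrings of the references; the returned frame records sequence,
    parent tRNA, origin, class and cut coordinates as ground truth.
    """
    cut_plan = dict(cut_plan or DEFAULT_CUT_PLAN)
    trh_prob = dict(trh_prob or DEFAULT_TRH_PROB)
    missing = set(refs) - set(landmarks.index)
    if missing:
        raise ValueError(f"landmark table missing tRNA: {sorted(missing)[0]}")
    for origin in cut_plan:
        if origin not in TSRNA_ORIGINS:
            raise ValueError(f"unknown origin {origin!r}")
    rng = np.random.default_rng(seed)
    origins = list(cut_plan)
    probs = np.array([cut_plan[o] for o in origins], dtype=float)
    probs /= probs.sum()
    ref_ids = list(refs)
    rows = []
    for i in range(n_reads):
        rid = ref_ids[int(rng.integers(0, len(ref_ids)))]
        lm = landmarks.loc[rid]
        seq = refs[rid]
        origin = origins[int(rng.choice(len(origins), p=probs))]
        is_trh = rng.random() < trh_prob.get(origin, 0.0)
        if is_trh:
            length = int(rng.integers(31, 37))
        else:
            length = int(rng.integers(14, 28))
        if origin == "5p_mature":
            start = int(lm["mature_start"])
        elif origin == "3p_mature":
            start = int(lm["mature_end"]) - length
        elif origin == "5p_precursor":
            is_trh = False
            length = min(length, int(lm["leader_len"]))
            start = int(rng.integers(0, lm["leader_len"] - length + 1))
        else:  # da_loop
            is_trh = False
            loop = "dloop" if rng.random() < 0.5 else "acloop"
            start = int(lm[f"{loop}_start"]) + int(rng.integers(0, 3))
            length = min(length, int(lm["mature_end"]) - 1 - start)
        rows.append({
            "read_id": f"ts{i:05d}", "seq": seq[start:start + length],
            "ref_id": rid, "aa": lm["aa"], "anticodon": lm["anticodon"],
            "origin": origin, "cls": "tRH" if is_trh else "tRF",
            "start": start, "length": length,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Small-RNA count matrices


def simulate_smallrna_counts(species_log2fc: pd.DataFrame,
                             baseline: pd.Series, n_reps: int = 4,
                             depth: float = 1e6,
                             dispersion: float = 0.04,
                             seed: int = 0) -> CountMatrix:
    """NB counts for a catalog of small-RNA species.

    ``species_log2fc`` is species x condition (control column implied at
    0); ``baseline`` gives relative abundances.
    """
    rng = np.random.default_rng(seed)
    species = list(species_log2fc.index)
    base = baseline.loc[species].to_numpy(dtype=float)
    base = base / base.sum()
    data, meta = {}, []
    for cond in ["control"] + list(species_log2fc.columns):
        lfc = (np.zeros(len(species)) if cond == "control"
               else species_log2fc[cond].to_numpy(dtype=float))
        mean = base * (2.0 ** lfc) * depth
        for rep in range(1, n_reps + 1):
            name = f"smallRNA_{cond}_{rep}"
            data[name] = _draw_nb(rng, mean, np.full(len(species), dispersion))
            meta.append({"sample": name, "assay": "smallRNA",
                         "condition": cond, "replicate": str(rep)})
    counts = pd.DataFrame(data, index=pd.Index(species, name="species"))
    return CountMatrix(counts, pd.DataFrame(meta).set_index("sample"))


# ---------------------------------------------------------------------------
# End-to-end experiment


@dataclass
class SimOutput:
    """Bundle of everything one simulated experiment produced."""

    config: SimConfig
    transcripts: list[Transcript]
    truth: SimTruth
    counts: dict[str, CountMatrix]
    rpf_reads: pd.DataFrame
    mirnas: dict[str, str]
    trna_refs: dict[str, str]
    trna_landmarks: pd.DataFrame
    tsrna_reads: pd.DataFrame
    smallrna_counts: CountMatrix


def simulate_experiment(config: SimConfig | None = None,
                        seed: int = 0) -> SimOutput:
    """Run the full generator under one configuration and seed."""
    cfg = config or SimConfig()
    root = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(8)]

    transcripts = make_transcriptome(
        cfg.n_genes, cfg.utr5_length, cfg.cds_codons, cfg.utr3_length,
        cfg.gc, seed=seeds[0])
    genes = [t.gene_id for t in transcripts]

    mirnas = random_mirnas(cfg.n_mirnas, seed=seeds[1])
    transcripts, planted, sites = plant_mirna_targets(
        transcripts, mirnas, cfg.mirna_site_probs, seed=seeds[2])
    n_up = (cfg.n_mirnas + 1) // 2
    up_ids = list(mirnas)[:n_up]
    mirna_lfc = {"0h": {mid: (cfg.mirna_log2fc if mid in up_ids
                              else -cfg.mirna_log2fc) for mid in mirnas},
                 "2h": {mid: 0.0 for mid in mirnas}}

    modes = {}
    for j, (contrast, mix) in enumerate(cfg.mode_mix.items()):
        modes[contrast] = plant_modes(genes, mix, cfg.effect_size,
                                      seed=seeds[3] + j)
    # canonical miRNA action: upregulated miRNAs repress target mRNA
    # abundance (per-site, saturating at 3 sites) without touching RPFs
    if cfg.mirna_effect_per_site and "0h" in modes:
        up_sites = sites[up_ids].sum(axis=1).clip(upper=3)
        modes["0h"]["mrna_log2fc"] = (
            modes["0h"]["mrna_log2fc"]
            - cfg.mirna_effect_per_site * up_sites.loc[modes["0h"].index])

    baseline = random_baseline(genes, cfg.abundance_sigma, seed=seeds[4])
    truth = SimTruth(
        genes=genes, baseline=baseline, modes=modes,
        dispersion=cfg.dispersion, psite_offset=cfg.psite_offset,
        frame_fidelity=cfg.frame_fidelity, leakage=cfg.leakage,
        init_peak=cfg.init_peak, mirna_seqs=dict(mirnas),
        mirna_log2fc=mirna_lfc, mirna_sites=sites)
    counts = simulate_counts(truth, cfg.n_reps, cfg.depth, seed=seeds[5])

    rpf_reads = simulate_rpf_reads(
        transcripts, baseline, cfg.psite_offset, cfg.frame_fidelity,
        cfg.read_lengths, cfg.n_rpf_reads, cfg.leakage, cfg.init_peak,
        seed=seeds[6])

    trna_refs, landmarks = make_trna_references(cfg.n_trnas, seed=seeds[7])
    tsrna_reads = simulate_tsrna_reads(trna_refs, landmarks,
                                       n_reads=cfg.n_tsrna_reads,
                                       seed=seeds[7])
    truth.tsrna_truth = tsrna_reads

    # species-level small-RNA counts: miRNAs plus the merged tsRNA species
    # observed in the cut reads; one 3' tRF species is planted 2-fold down
    species_origin = tsrna_reads.groupby(
        ["aa", "anticodon", "origin", "cls"]).size()
    ts_ids = [f"{aa}{ac}-{cls}-{ORIGIN_SUFFIX[origin]}"
              for (aa, ac, origin, cls) in species_origin.index]
    all_species = list(mirnas) + ts_ids
    down_trf = next((s for s in ts_ids if s.endswith("-tRF-3")), None)
    sp_lfc = pd.DataFrame(0.0, index=all_species, columns=["0h", "2h"])
    for mid in mirnas:
        sp_lfc.loc[mid, "0h"] = mirna_lfc["0h"][mid]
    if down_trf is not None:
        sp_lfc.loc[down_trf, "0h"] = cfg.tsrna_down_log2fc
    sp_base = random_baseline(all_species, sigma=0.5, seed=seeds[5] + 1)
    smallrna_counts = simulate_smallrna_counts(
        sp_lfc, sp_base, cfg.n_reps, cfg.smallrna_depth, cfg.dispersion,
        seed=seeds[5] + 2)
    truth.smallrna_log2fc = {c: sp_lfc[c].to_dict() for c in sp_lfc.columns}

    return SimOutput(cfg, transcripts, truth, counts, rpf_reads, mirnas,
                     trna_refs, landmarks, tsrna_reads, smallrna_counts)
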