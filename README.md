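# ribopulse

Integrative post-transcriptional analysis of matched ribosome-profiling
(Ribo-seq), mRNA-seq and small-RNA-seq count data, built for stimulation
time-course designs — e.g. neuronal cultures harvested immediately and
2 h after repeated K⁺ depolarization, in biological quadruplicate.  The
package ships a ground-truth simulator that plants known regulatory
structure, so every stage of the analysis can be validated by parameter
recovery rather than by eye.

## What it computes

**Ribo-seq QC** (`ribopulse.riboqc`) — feature mapping rates over
5′UTR/CDS/3′UTR, metagene density profiles around start/stop codons,
per-read-length P-site offset calibration by start-codon
cross-correlation, and sub-codon phasing.  A translating ribosome
protects a footprint whose P-site sits a fixed offset downstream of the
read 5′ end; real libraries show ~80 % of P-sites in reading frame 0.

**Differential expression and translational efficiency**
(`ribopulse.diffexpr`) — counts are CPM-filtered and TMM-normalized, NB
dispersion φ (var = μ + φμ²) is estimated by moments with shrinkage to a
common value, and each contrast is tested with a double-tail NB exact
test on group sums.  Significance uses Benjamini–Hochberg FDR < 0.05 and
|log₂FC| > 0.5.  Translational efficiency (TE = ribosome occupancy per
mRNA) is tested per gene with the NB log-linear model

    log μ = offset + β₀ + β_assay·I(RPF) + β_cond·I(treated) + β_int·I(RPF)·I(treated)

where Δlog₂TE = β_int/ln 2 and the p-value is a 1-df likelihood-ratio
test of β_int = 0.

**Regulatory modes** (`ribopulse.regmode`) — each gene is classified
from its paired mRNA/RPF calls as homodirectional, opposite,
transcriptional (mRNA only — post-transcriptional buffering),
translational (RPF only) or stable, with buffering summarized as the
transcriptional:translational ratio.

**Sequence features** (`ribopulse.seqfeat`) — per-region length, GC%,
length-normalized minimum free energy from a Nussinov-style pairing DP
(GC −3, AU −2, GU −1, loop ≥ 3), G-quadruplex regions from a
G4Hunter-style run score, upstream-AUG counts and rare-codon frequency;
genes are binned into feature quartiles and fold-change distributions
compared by Kruskal–Wallis.

**Small RNAs** (`ribopulse.smallrna`) — miRNA/tRF targets are genes
whose 3′UTR contains the reverse complement of small-RNA nucleotides 2–8
(the seed); target fold-change CDFs, stratified by site count (1, 2, ≥3),
are compared to the zero-site background with two-sided
Kolmogorov–Smirnov tests.  tRNA-derived small RNAs are mapped to tRNA
references by tiered mismatch matching, classified by cloverleaf
landmark (5′/3′ mature, D/anticodon loop, 5′ precursor) and length class
(tRF 14–30 nt, tRH 28–36 nt), merged per (amino acid, anticodon, origin,
class) species, and tested for differential expression after a
CPM > 100 robust-expression filter.

**Simulator** (`ribopulse.simulate`) — generates the transcriptome,
plants per-gene regulatory modes and miRNA sites, draws NB counts for
4 replicates × {control, 0 h, 2 h}, emits RPF reads with a planted
P-site offset and frame fidelity, and cuts tsRNA reads from synthetic
tRNA references, recording all ground truth.

## Worked example

```python
import pandas as pd
from ribopulse import diffexpr, regmode, simulate

out = simulate.simulate_experiment(simulate.SimConfig(n_genes=1000), seed=42)

def de(cm, treated="0h"):
    a = cm.samples_for(condition=treated); b = cm.samples_for(condition="control")
    sub = cm.subset(a + b)
    factors = diffexpr.tmm_factors(sub)
    phi, common = diffexpr.estimate_dispersion(sub, factors=factors)
    return diffexpr.exact_test(sub, a, b, phi, factors), common

mrna_de, phi_m = de(out.counts["mRNA"])
rpf_de, phi_r = de(out.counts["RPF"])
print(f"common dispersion: mRNA {phi_m:.3f}, RPF {phi_r:.3f}")
print(f"significant at 0 h: mRNA {int(mrna_de.significant.sum())}, "
      f"RPF {int(rpf_de.significant.sum())} of {len(mrna_de)} genes")
table = regmode.classify_modes(mrna_de, rpf_de)
print(regmode.buffering_summary(table)["counts"])
truth = out.truth.modes["0h"]["mode"]
print(f"agreement with planted modes: "
      f"{(table['mode'] == truth.loc[table.index]).mean():.1%}")
```

prints

```
common dispersion: mRNA 0.037, RPF 0.036
significant at 0 h: mRNA 425, RPF 238 of 1000 genes
{'homodirectional': 46, 'opposite': 30, 'transcriptional': 349, 'translational': 162, 'stable': 413}
agreement with planted modes: 93.2%
```

The estimated common dispersion recovers the generator's φ = 0.04; the
transcription-heavy 0 h mode mix shows up as an excess of
transcriptional over translational calls (349 vs 162 — the buffering
signature), and 93 % of genes get their planted regulatory mode back.

A command-line interface mirrors the library:

```sh
ribopulse simulate --config sim.yaml --outdir sim/
ribopulse qc --reads sim/rpf_reads.tsv --transcripts sim/transcripts.fasta
ribopulse de --counts sim/counts_mRNA.tsv --treated 0h --control control
ribopulse modes --mrna de_mrna.tsv --rpf de_rpf.tsv
ribopulse tsrna --reads sim/tsrna_reads.tsv --refs sim/trna_refs.fasta \
    --landmarks sim/trna_landmarks.tsv
```

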