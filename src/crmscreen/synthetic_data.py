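"""Synthetic fixtures with planted ground truth for every pipeline stage.

The locus generator emulates the statistical structure of a real screen: a
pairwise-aligned locus with 49 planted conserved blocks (12 of which carry
three or more active chromatin-mark types and no repressive mark, split 10
upstream / 2 downstream of the planted gene), decoy blocks that must be
removed by the exon / blacklist / length filters, planted binding-site
consensus sequences, peak tracks per mark, a contact matrix, CTCF and ATAC
peaks. The other generators produce block-structured contact matrices,
bimodal marker expression matrices and normalized-fluorescence tables.
Every generator is deterministic given (config, seed); one master seed fans
out to per-component substreams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_core import (
    ContactMatrix,
    GenomicInterval,
    SequenceRecord,
    write_bed,
    write_contact_matrix,
    write_fasta,
)

__all__ = [
    "LocusConfig",
    "SyntheticLocus",
    "synth_locus",
    "synth_contact_matrix",
    "synth_expression",
    "synth_fluorescence",
    "ETS_SYN_COUNTS",
    "TCF_SYN_COUNTS",
]

BASES = np.array(list("ACGT"))

ACTIVE_MARKS = ("H3K27ac", "H3K4me2", "p300", "RNAP2", "Med12")
REPRESSIVE_MARK = "H3K27me3"

# Synthetic JASPAR-style count matrices. ETS_SYN contains the Ets core GGAA;
# TCF_SYN contains the Tcf/Lef core SCTTTGATS (S positions split C/G).
_ETS_CONSENSUS = "CCGGAAGT"
ETS_SYN_COUNTS = np.full((4, len(_ETS_CONSENSUS)), 1, dtype=int)
for _j, _b in enumerate(_ETS_CONSENSUS):
    ETS_SYN_COUNTS["ACGT".index(_b), _j] = 97

_TCF_CONSENSUS = "CCTTTGATC"
TCF_SYN_COUNTS = np.full((4, len(_TCF_CONSENSUS)), 2, dtype=int)
for _j, _b in enumerate(_TCF_CONSENSUS):
    TCF_SYN_COUNTS["ACGT".index(_b), _j] = 94
# degenerate S (C/G) at the first and last core positions
TCF_SYN_COUNTS[:, 0] = np.array([2, 48, 48, 2])
TCF_SYN_COUNTS[:, -1] = np.array([2, 48, 48, 2])


def _rand_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=n)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, p: float) -> np.ndarray:
    """Copy with each base substituted (to a different base) with prob p."""
    out = seq.copy()
    flip = rng.random(seq.size) < p
    idx = np.flatnonzero(flip)
    for i in idx:
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return out


@dataclass
class LocusConfig:
    """Study conditions of the synthetic screen fixture."""

    n_blocks: int = 49
    n_positive_upstream: int = 10
    n_positive_downstream: int = 2
    n_upstream_blocks: int = 41          # blocks before the gene
    block_len_range: tuple[int, int] = (300, 1900)
    spacer_len_range: tuple[int, int] = (300, 800)
    block_identity_range: tuple[float, float] = (0.90, 1.0)
    gene_len: int = 6000
    promoter_flank: int = 500
    n_veto_negatives: int = 3            # negatives with >=3 marks but repressive
    chrom: str = "chr_syn"
    bin_bp: int = 1500
    # the locus matrix exists for the same-TAD annotation; it is noise-free so
    # the planted single-domain truth is exact (the standalone contact-matrix
    # generator carries the noisy conditions for exercising the TAD caller)
    matrix_noise_cv: float = 0.0
    n_accessible_negatives: int = 5

    def __post_init__(self) -> None:
        if self.n_positive_upstream > self.n_upstream_blocks:
            raise ValueError("more upstream positives than upstream blocks")
        if self.n_positive_downstream > self.n_blocks - self.n_upstream_blocks:
            raise ValueError("more downstream positives than downstream blocks")


@dataclass
class SyntheticLocus:
    """Generated locus data plus the planted truth."""

    config: LocusConfig
    seed: int
    ref: SequenceRecord
    other: SequenceRecord
    blocks: list[GenomicInterval]             # the n_blocks real planted blocks
    block_identities: list[float]
    positive_indices: list[int]               # indices into blocks
    marks_per_block: list[tuple[str, ...]]    # mark types assigned per block
    peak_tracks: dict[str, list[GenomicInterval]]
    exons: list[GenomicInterval]
    gene: GenomicInterval
    promoter: GenomicInterval
    blacklist: list[GenomicInterval]
    decoys: dict[str, GenomicInterval]        # label -> planted decoy block
    expected_labels: dict[int, int]           # positive block index -> signed label
    accessible_indices: list[int]
    contact: ContactMatrix
    ctcf_peaks: list[GenomicInterval]
    atac_peaks: list[GenomicInterval]

    def truth_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_blocks": len(self.blocks),
            "n_positive": len(self.positive_indices),
            "blocks": [[b.start, b.end] for b in self.blocks],
            "block_identities": self.block_identities,
            "positive_indices": list(self.positive_indices),
            "expected_labels": {str(k): v for k, v in self.expected_labels.items()},
            "marks_per_block": [list(m) for m in self.marks_per_block],
            "promoter": [self.promoter.start, self.promoter.end],
            "gene": [self.gene.start, self.gene.end, self.gene.strand],
            "accessible_indices": list(self.accessible_indices),
            "decoys": {k: [v.start, v.end] for k, v in self.decoys.items()},
        }

    def write(self, outdir: str | Path) -> dict:
        """Write all standard-format files plus a manifest JSON; returns the
        manifest (paths + truth)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        # manifest paths are relative to the manifest's directory, so the
        # fixture directory is relocatable and byte-identical across runs
        names = {
            "alignment": "alignment.fasta",
            "annotation": "annotation.gff3",
            "blacklist": "blacklist.bed",
            "pwms": "motifs.pfm",
            "matrix": "contacts.tsv",
            "bins": "bins.bed",
            "ctcf": "ctcf.bed",
            "atac": "atac.bed",
        }
        write_fasta([self.ref, self.other], outdir / names["alignment"])
        self._write_gff3(outdir / names["annotation"])
        write_bed(self.blacklist, outdir / names["blacklist"])
        (outdir / names["pwms"]).write_text(jaspar_text())
        write_contact_matrix(self.contact, outdir / names["matrix"], outdir / names["bins"])
        write_bed(self.ctcf_peaks, outdir / names["ctcf"])
        write_bed(self.atac_peaks, outdir / names["atac"])
        peaks = {}
        for mark, ivs in self.peak_tracks.items():
            name = f"peaks_{mark}.bed"
            write_bed(ivs, outdir / name)
            peaks[mark] = name
        manifest = {
            "paths": names,
            "peaks": peaks,
            "truth": self.truth_dict(),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest

    def _write_gff3(self, path: Path) -> None:
        c = self.config.chrom
        lines = ["##gff-version 3"]
        g = self.gene
        lines.append(
            f"{c}\tsynth\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID=gene1"
        )
        for k, e in enumerate(self.exons, 1):
            lines.append(
                f"{c}\tsynth\texon\t{e.start + 1}\t{e.end}\t.\t{g.strand}\t.\tID=exon{k};Parent=gene1"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def jaspar_text() -> str:
    """The synthetic PWM set in JASPAR flat format."""
    out = []
    for name, counts in (("ETS_SYN", ETS_SYN_COUNTS), ("TCF_SYN", TCF_SYN_COUNTS)):
        out.append(f">{name} {name}")
        for b, row in zip("ACGT", counts):
            out.append(f"{b} [ " + " ".join(str(int(x)) for x in row) + " ]")
    return "\n".join(out) + "\n"


def synth_locus(config: LocusConfig | None = None, seed: int = 0,
                outdir: str | Path | None = None) -> SyntheticLocus:
    """Generate the full screen fixture; see the module docstring.

    Planted real blocks are sized and spaced so the conservation caller
    (window 100, threshold 0.7) recovers each within half a window per edge
    and never merges neighbours; decoy blocks (too short, too long,
    exon-overlapping, blacklisted) are planted to be removed by the filters.
    """
    cfg = config or LocusConfig()
    ss = np.random.SeedSequence(seed)
    rng_seq, rng_marks, rng_matrix, rng_assign = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    lo_len, hi_len = cfg.block_len_range
    lo_sp, hi_sp = cfg.spacer_len_range

    # --- layout: element list in genomic order ------------------------------
    # decoy insertion points among the upstream blocks
    elements: list[tuple[str, int]] = []  # (kind, length)
    block_lens = rng_seq.integers(lo_len, hi_len + 1, size=cfg.n_blocks)
    bi = 0
    for i in range(cfg.n_upstream_blocks):
        if i == 5:
            elements.append(("decoy_short", 100))
        if i == 20:
            elements.append(("decoy_long", 2400))
        if i == 30:
            elements.append(("decoy_blacklist", int(rng_seq.integers(lo_len, hi_len))))
        elements.append(("block", int(block_lens[bi])))
        bi += 1
    elements.append(("gene", cfg.gene_len))
    for i in range(cfg.n_upstream_blocks, cfg.n_blocks):
        elements.append(("block", int(block_lens[bi])))
        bi += 1

    blocks: list[GenomicInterval] = []
    decoys: dict[str, GenomicInterval] = {}
    gene: GenomicInterval | None = None
    cursor = 0
    placed: list[tuple[str, GenomicInterval]] = []
    for kind, length in elements:
        spacer = int(rng_seq.integers(lo_sp, hi_sp + 1))
        if kind == "gene":
            spacer = max(spacer, cfg.promoter_flank + 300)
        cursor += spacer
        iv = GenomicInterval(cfg.chrom, cursor, cursor + length,
                             strand="+" if kind == "gene" else ".")
        placed.append((kind, iv))
        if kind == "block":
            blocks.append(iv)
        elif kind == "gene":
            gene = iv
        else:
            decoys[kind] = iv
        cursor += length
    cursor += int(rng_seq.integers(lo_sp, hi_sp + 1))
    locus_len = cursor
    assert gene is not None

    tss = gene.start
    promoter = GenomicInterval(cfg.chrom, tss - cfg.promoter_flank,
                               tss + cfg.promoter_flank, name="promoter")
    exons = [
        GenomicInterval(cfg.chrom, gene.start + 1000, gene.start + 1200, name="exon1"),
        GenomicInterval(cfg.chrom, gene.start + 2500, gene.start + 2700, name="exon2"),
        GenomicInterval(cfg.chrom, gene.start + 4000, gene.start + 4300, name="exon3"),
    ]
    # exon-overlap decoy conserved segments (inside the gene, over exons 1, 2)
    decoys["decoy_exon1"] = GenomicInterval(cfg.chrom, exons[0].start - 100, exons[0].end + 100)
    decoys["decoy_exon2"] = GenomicInterval(cfg.chrom, exons[1].start - 100, exons[1].end + 100)
    blacklist = [
        GenomicInterval(cfg.chrom, decoys["decoy_blacklist"].start - 50,
                        decoys["decoy_blacklist"].end + 50, name="prior_element")
    ]

    # --- sequences ----------------------------------------------------------
    ref = _rand_seq(rng_seq, locus_len)
    other = _rand_seq(rng_seq, locus_len)  # background: unrelated (~25% identity)

    block_identities: list[float] = []
    conserved_items: list[tuple[GenomicInterval, float]] = []
    for b in blocks:
        ident = float(rng_seq.uniform(*cfg.block_identity_range))
        block_identities.append(ident)
        conserved_items.append((b, ident))
    for label, d in decoys.items():
        conserved_items.append((d, 0.95))
    for iv, ident in conserved_items:
        other[iv.start : iv.end] = _mutate(rng_seq, ref[iv.start : iv.end], 1.0 - ident)

    # planted binding sites: identical in both species, centred in each block
    ets = np.array(list(_ETS_CONSENSUS))
    tcf = np.array(list(_TCF_CONSENSUS))
    for i, b in enumerate(blocks):
        mid = (b.start + b.end) // 2
        ref[mid : mid + ets.size] = ets
        other[mid : mid + ets.size] = ets
        ref[mid + 20 : mid + 20 + tcf.size] = tcf
        other[mid + 20 : mid + 20 + tcf.size] = tcf

    ref_rec = SequenceRecord("ref", "".join(ref))
    other_rec = SequenceRecord("other", "".join(other))

    # --- positive selection and marks ---------------------------------------
    upstream_ids = list(range(cfg.n_upstream_blocks))
    downstream_ids = list(range(cfg.n_upstream_blocks, cfg.n_blocks))
    pos_up = sorted(rng_assign.choice(upstream_ids, cfg.n_positive_upstream, replace=False))
    pos_down = sorted(rng_assign.choice(downstream_ids, cfg.n_positive_downstream, replace=False))
    positives = [int(i) for i in pos_up + pos_down]
    pos_set = set(positives)

    negatives = [i for i in range(cfg.n_blocks) if i not in pos_set]
    veto = set(
        int(i) for i in rng_assign.choice(negatives, cfg.n_veto_negatives, replace=False)
    )

    marks_per_block: list[tuple[str, ...]] = []
    peak_tracks: dict[str, list[GenomicInterval]] = {m: [] for m in ACTIVE_MARKS}
    peak_tracks[REPRESSIVE_MARK] = []
    for i, b in enumerate(blocks):
        if i in pos_set:
            k = int(rng_marks.integers(3, len(ACTIVE_MARKS) + 1))
            marks = list(rng_marks.choice(ACTIVE_MARKS, k, replace=False))
        elif i in veto:
            k = int(rng_marks.integers(3, len(ACTIVE_MARKS) + 1))
            marks = list(rng_marks.choice(ACTIVE_MARKS, k, replace=False))
            marks.append(REPRESSIVE_MARK)
        else:
            k = int(rng_marks.integers(0, 3))
            marks = list(rng_marks.choice(ACTIVE_MARKS, k, replace=False))
        marks_per_block.append(tuple(marks))
        for m in marks:
            j0 = int(rng_marks.integers(0, 31))
            j1 = int(rng_marks.integers(0, 31))
            peak_tracks[m].append(
                GenomicInterval(cfg.chrom, max(0, b.start - j0), b.end + j1,
                                name=f"{m}_block{i}")
            )

    # --- expected signed labels for the planted positives -------------------
    pmid = promoter.midpoint
    expected_labels: dict[int, int] = {}
    up_sorted = sorted(pos_up, key=lambda i: (abs(blocks[i].midpoint - pmid), blocks[i].start))
    for rank, i in enumerate(up_sorted, 1):
        expected_labels[int(i)] = -rank
    down_sorted = sorted(pos_down, key=lambda i: (abs(blocks[i].midpoint - pmid), blocks[i].start))
    for rank, i in enumerate(down_sorted, 1):
        expected_labels[int(i)] = rank

    # --- contact matrix (single TAD spanning the locus), CTCF, ATAC ---------
    n_bins = -(-locus_len // cfg.bin_bp)  # ceil: bins must cover the locus
    contact = _block_matrix(
        n_bins=n_bins, bin_bp=cfg.bin_bp, boundaries=[], intra_mean=1.0,
        inter_mean=0.2, noise_cv=cfg.matrix_noise_cv, rng=rng_matrix,
        chrom=cfg.chrom,
    )
    ctcf_peaks = [
        GenomicInterval(cfg.chrom, 0, 200, name="CTCF_left"),
        GenomicInterval(cfg.chrom, locus_len - 200, locus_len, name="CTCF_right"),
    ]
    acc_neg = [int(i) for i in rng_assign.choice(
        [i for i in negatives if i not in veto], cfg.n_accessible_negatives, replace=False
    )]
    accessible = sorted(pos_set | set(acc_neg))
    atac_peaks = [
        GenomicInterval(cfg.chrom, blocks[i].start - 10, blocks[i].end + 10,
                        name=f"atac_block{i}")
        for i in accessible
    ]

    locus = SyntheticLocus(
        config=cfg, seed=seed, ref=ref_rec, other=other_rec, blocks=blocks,
        block_identities=block_identities, positive_indices=positives,
        marks_per_block=marks_per_block, peak_tracks=peak_tracks, exons=exons,
        gene=gene, promoter=promoter, blacklist=blacklist, decoys=decoys,
        expected_labels=expected_labels, accessible_indices=list(accessible),
        contact=contact, ctcf_peaks=ctcf_peaks, atac_peaks=atac_peaks,
    )
    if outdir is not None:
        locus.write(outdir)
    return locus


def _block_matrix(
    n_bins: int,
    bin_bp: int,
    boundaries: Sequence[int],
    intra_mean: float,
    inter_mean: float,
    noise_cv: float,
    rng: np.random.Generator,
    chrom: str = "chr_syn",
) -> ContactMatrix:
    domain = np.zeros(n_bins, dtype=int)
    for b in boundaries:
        if not (0 < b < n_bins):
            raise ValueError(f"boundary index {b} outside (0, {n_bins})")
        domain[b:] += 1
    base = np.where(domain[:, None] == domain[None, :], intra_mean, inter_mean)
    if noise_cv > 0:
        sigma2 = np.log1p(noise_cv**2)
        noise = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=(n_bins, n_bins))
        noise = np.triu(noise) + np.triu(noise, k=1).T  # symmetric noise field
        m = base * noise
    else:
        m = base.astype(float)
    bins = [
        GenomicInterval(chrom, i * bin_bp, (i + 1) * bin_bp, name=f"bin{i}")
        for i in range(n_bins)
    ]
    return ContactMatrix(bins=bins, matrix=m)


def synth_contact_matrix(
    n_bins: int = 80,
    bin_bp: int = 1500,
    boundaries: Sequence[int] = (30, 50),
    intra_mean: float = 1.0,
    inter_mean: float = 0.2,
    noise_cv: float = 0.3,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> tuple[ContactMatrix, dict]:
    """Block-diagonal contact matrix with multiplicative lognormal noise.

    ``boundaries`` are bin indices starting new domains; the truth dict
    echoes them for scoring a TAD caller. With ``noise_cv=0`` the matrix is
    exactly block-constant.
    """
    if inter_mean >= intra_mean:
        raise ValueError("inter_mean must be < intra_mean")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cm = _block_matrix(n_bins, bin_bp, list(boundaries), intra_mean, inter_mean,
                       noise_cv, rng)
    truth = {
        "boundaries": [int(b) for b in boundaries],
        "n_bins": n_bins,
        "bin_bp": bin_bp,
        "intra_mean": intra_mean,
        "inter_mean": inter_mean,
        "noise_cv": noise_cv,
        "seed": seed,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_contact_matrix(cm, outdir / "contacts.tsv", outdir / "bins.bed")
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return cm, truth


def synth_expression(
    n_cells: int = 500,
    marker_fraction: float = 0.4,
    p1: float = 0.8,
    p2: float = 0.1,
    n_candidates: int = 3,
    seed: int = 0,
    marker_gene: str = "Lhx2",
    outdir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Cells x genes matrix with a bimodal marker and planted co-expression.

    Candidate transcripts are "on" (value >= 0.5) with probability ``p1`` in
    marker-positive cells and ``p2`` in marker-negative cells; off-values are
    strictly below the 0.5 threshold.
    """
    if n_cells < 10:
        raise ValueError("n_cells must be >= 10")
    for p in (marker_fraction, p1, p2):
        if not (0 <= p <= 1):
            raise ValueError("probabilities must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    marker_pos = rng.random(n_cells) < marker_fraction

    def on_values(n: int) -> np.ndarray:
        return 0.5 + np.abs(rng.normal(1.0, 0.5, size=n))

    def off_values(n: int) -> np.ndarray:
        return rng.uniform(0.0, 0.5, size=n)

    cols = {}
    marker = np.where(marker_pos, on_values(n_cells), off_values(n_cells))
    cols[marker_gene] = marker
    base_names = ["Etv4", "Etv5", "Tcf7", "Lef1", "Msx1", "Meis2"]
    names = [base_names[i] if i < len(base_names) else f"cand{i + 1}"
             for i in range(n_candidates)]
    for g in names:
        on = np.where(marker_pos, rng.random(n_cells) < p1, rng.random(n_cells) < p2)
        cols[g] = np.where(on, on_values(n_cells), off_values(n_cells))
    mat = pd.DataFrame(cols, index=[f"cell{i}" for i in range(n_cells)])
    truth = {
        "marker_gene": marker_gene,
        "candidates": names,
        "n_marker_pos": int(marker_pos.sum()),
        "p1": p1,
        "p2": p2,
        "seed": seed,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mat.to_csv(outdir / "expression.tsv", sep="\t")
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return mat, truth


DEFAULT_FLUOR_GROUPS: dict[str, tuple[int, float]] = {
    # construct -> (n embryos, effect in control-SD units); sizes mirror a
    # typical disruption series with a wildtype construct as control
    "CRM_WT": (28, 0.0),
    "dETS": (19, -2.0),
    "dTCF": (9, -4.0),
    "dETS_TCF": (16, -4.0),
    "empty": (15, -4.0),
}


def synth_fluorescence(
    groups: Mapping[str, tuple[int, float]] | None = None,
    control_sd: float = 0.15,
    rfp_mean: float = 1000.0,
    rfp_cv: float = 0.2,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-embryo fluorescence records with planted group effects.

    The normalized (GFP/RFP) value is Normal(1 + effect*control_sd,
    control_sd) truncated at 0; RFP is lognormal around ``rfp_mean`` and GFP
    = normalized * RFP.
    """
    groups = dict(groups or DEFAULT_FLUOR_GROUPS)
    if control_sd <= 0:
        raise ValueError("control_sd must be positive")
    for g, (n, _e) in groups.items():
        if n < 2:
            raise ValueError(f"group {g!r} needs n >= 2")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for g, (n, effect) in groups.items():
        normalized = np.clip(
            rng.normal(1.0 + effect * control_sd, control_sd, size=n), 1e-6, None
        )
        sigma2 = np.log1p(rfp_cv**2)
        rfp = rng.lognormal(np.log(rfp_mean) - sigma2 / 2, np.sqrt(sigma2), size=n)
        for k in range(n):
            rows.append(
                {
                    "embryo_id": f"{g}_{k + 1}",
                    "group": g,
                    "gfp_mean": normalized[k] * rfp[k],
                    "rfp_mean": rfp[k],
                }
            )
    df = pd.DataFrame(rows)
    truth = {
        "groups": {g: {"n": n, "effect_sd": e} for g, (n, e) in groups.items()},
        "control_sd": control_sd,
        "seed": seed,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "fluorescence.tsv", sep="\t", index=False)
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return df, truth
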