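"""End-to-end candidate screen: conservation -> filters -> binding sites ->
mark evidence -> signed labels -> 3D/accessibility annotation.

Stages run in a fixed order with per-stage input/output counts logged. TAD
membership and accessibility are annotations by default (they supported, but
did not drive, candidate selection); ``require_same_tad`` /
``require_accessible`` turn them into filters.
"""

from __future__ import annotations

import importlib.metadata
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import chromatin_3d, conservation, evidence, motif_scan
from .genome_core import (
    ContactMatrix,
    GenomicInterval,
    SequenceRecord,
    parse_contact_matrix,
    parse_fasta,
    parse_intervals,
)

__all__ = ["ScreenConfig", "ScreenReport", "screen_locus", "screen_from_manifest"]


@dataclass
class ScreenConfig:
    """Input paths and parameters for one screen run.

    ``peaks`` maps mark name -> BED path. The promoter is derived from the
    named gene feature in the GFF3 as TSS +/- ``promoter_flank``. Contact
    matrix, CTCF and ATAC inputs are optional; the corresponding report
    columns degrade to missing values with a warning.
    """

    alignment: str
    annotation: str
    blacklist: str
    peaks: dict[str, str]
    pwms: str
    gene_id: str = "gene1"
    active_marks: frozenset[str] = evidence.DEFAULT_ACTIVE_MARKS
    repressive_marks: frozenset[str] = evidence.DEFAULT_REPRESSIVE_MARKS
    min_identity: float = 0.7
    window_bp: int = 100
    min_len: int = 150
    max_len: int = 2100
    min_marks: int = 3
    tfbs_alpha: float = 1e-2
    promoter_flank: int = 500
    matrix: str | None = None
    bins: str | None = None
    ctcf: str | None = None
    atac: str | None = None
    tad_threshold: float = 0.05
    tad_delta: float = 0.01
    tad_min_depth_bp: int = 3000
    tad_max_depth_bp: int = 31500
    require_same_tad: bool = False
    require_accessible: bool = False

    def required_paths(self) -> dict[str, str]:
        req = {"alignment": self.alignment, "annotation": self.annotation,
               "blacklist": self.blacklist, "pwms": self.pwms}
        req.update({f"peaks[{m}]": p for m, p in self.peaks.items()})
        return req


@dataclass
class ScreenReport:
    """Ranked candidate table plus the stage log and a config echo."""

    table: pd.DataFrame
    stage_log: list[dict]
    config_echo: dict
    version: str = field(default_factory=lambda: _version())

    def to_tsv(self, path: str | Path) -> None:
        df = self.table.copy()
        if "identity" in df.columns:
            df["identity"] = df["identity"].map(lambda x: f"{x:.4f}")
        df.to_csv(path, sep="\t", index=False)

    def write_manifest(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"config": self.config_echo, "version": self.version,
                 "stage_log": self.stage_log},
                indent=1, sort_keys=True, default=str,
            )
        )


def _version() -> str:
    try:
        return importlib.metadata.version("crmscreen")
    except importlib.metadata.PackageNotFoundError:
        return "unknown"


def _read_gene_and_exons(path: str, gene_id: str):
    feats = parse_intervals(path, "GFF3")
    gene = None
    exons = []
    for f in feats:
        ftype = getattr(f, "feature_type", "")
        if ftype == "gene" and f.name == gene_id:
            gene = f
        elif ftype == "exon":
            exons.append(f)
    if gene is None:
        raise ValueError(f"gene {gene_id!r} not found in {path}")
    return gene, exons


def screen_locus(config: ScreenConfig) -> ScreenReport:
    """Run the full screen from files named in the config.

    All required inputs are checked before any computation; optional inputs
    that are missing demote their columns to NA with a warning. Stage errors
    propagate tagged with the stage name. Deterministic given inputs.
    """
    missing = [f"{k}: {v}" for k, v in config.required_paths().items()
               if not Path(v).exists()]
    for opt in ("matrix", "bins", "ctcf", "atac"):
        p = getattr(config, opt)
        if p is not None and not Path(p).exists():
            missing.append(f"{opt}: {p}")
    if missing:
        raise FileNotFoundError("missing input(s): " + "; ".join(missing))

    records = parse_fasta(config.alignment, aligned=True)
    if len(records) < 2:
        raise ValueError("alignment must contain reference and one other species")
    ref, other = records[0], records[1]
    gene, exons = _read_gene_and_exons(config.annotation, config.gene_id)
    blacklist = parse_intervals(config.blacklist, "BED")
    peak_tracks = {m: parse_intervals(p, "BED") for m, p in config.peaks.items()}
    pwms = motif_scan.parse_jaspar(config.pwms)

    tss = gene.start if gene.strand != "-" else gene.end
    promoter = GenomicInterval(
        gene.chrom, tss - config.promoter_flank, tss + config.promoter_flank,
        name="promoter",
    )

    cm = ctcf = atac = None
    if config.matrix is not None and config.bins is not None:
        cm = parse_contact_matrix(config.matrix, config.bins)
    if config.ctcf is not None:
        ctcf = parse_intervals(config.ctcf, "BED")
    if config.atac is not None:
        atac = parse_intervals(config.atac, "BED")

    report = _screen(
        ref=ref, other=other, chrom=gene.chrom, gene_strand=gene.strand,
        promoter=promoter, exons=exons, blacklist=blacklist,
        peak_tracks=peak_tracks, pwms=pwms, cm=cm, ctcf_peaks=ctcf,
        atac_peaks=atac, config=config,
    )
    report.config_echo = {
        k: (sorted(v) if isinstance(v, frozenset) else v)
        for k, v in vars(config).items()
    }
    return report


def screen_from_manifest(manifest_path: str | Path, **overrides) -> ScreenReport:
    """Run the screen on files listed in a generator manifest JSON.

    Manifest paths are resolved relative to the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    man = json.loads(manifest_path.read_text())
    base = manifest_path.parent

    def resolve(p):
        return str(base / p) if p is not None else None

    paths = man["paths"]
    cfg = ScreenConfig(
        alignment=resolve(paths["alignment"]), annotation=resolve(paths["annotation"]),
        blacklist=resolve(paths["blacklist"]), pwms=resolve(paths["pwms"]),
        peaks={m: resolve(p) for m, p in man["peaks"].items()},
        matrix=resolve(paths.get("matrix")), bins=resolve(paths.get("bins")),
        ctcf=resolve(paths.get("ctcf")), atac=resolve(paths.get("atac")),
        **overrides,
    )
    return screen_locus(cfg)


def _stage(log: list[dict], name: str, n_in: int, n_out: int) -> None:
    log.append({"stage": name, "n_in": n_in, "n_out": n_out})


def _screen(
    ref: SequenceRecord,
    other: SequenceRecord,
    chrom: str,
    gene_strand: str,
    promoter: GenomicInterval,
    exons: Sequence[GenomicInterval],
    blacklist: Sequence[GenomicInterval],
    peak_tracks: Mapping[str, Sequence[GenomicInterval]],
    pwms: Sequence[motif_scan.PWM],
    cm: ContactMatrix | None,
    ctcf_peaks: Sequence[GenomicInterval] | None,
    atac_peaks: Sequence[GenomicInterval] | None,
    config: ScreenConfig,
) -> ScreenReport:
    log: list[dict] = []

    def run(stage: str, fn):
        try:
            return fn()
        except Exception as e:
            raise RuntimeError(f"stage {stage!r} failed: {e}") from e

    profile = run("conservation", lambda: conservation.window_identity(
        ref.seq, other.seq, config.window_bp))
    regions = run("conservation", lambda: conservation.call_conserved_regions(
        profile, config.min_identity, config.window_bp, chrom=chrom))
    _stage(log, "conservation", len(profile), len(regions))

    filtered = run("filter", lambda: conservation.filter_candidates(
        regions, exons=exons, blacklist=blacklist,
        min_len=config.min_len, max_len=config.max_len))
    _stage(log, "length_exon_blacklist_filter", len(regions), len(filtered))

    ref_seq = ref.ungapped()
    dists = [motif_scan.score_distribution(p) for p in pwms]

    def has_tfbs(region: conservation.ConservedRegion) -> bool:
        sub = ref_seq[region.interval.start : region.interval.end]
        return any(
            motif_scan.scan_sequence(sub, p, config.tfbs_alpha, dist=d)
            for p, d in zip(pwms, dists)
        )

    with_tfbs = run("tfbs", lambda: [
        (r, has_tfbs(r)) for r in filtered
    ])
    tfbs_pass = [r for r, ok in with_tfbs if ok]
    _stage(log, "tfbs_presence", len(filtered), len(tfbs_pass))

    profiles = run("marks", lambda: [
        evidence.count_marks(
            r, peak_tracks, config.active_marks, config.repressive_marks,
            has_tfbs=True,
        )
        for r in tfbs_pass
    ])
    accepted = [p for p in profiles if evidence.classify_pcrm(p, config.min_marks)]
    _stage(log, "mark_evidence", len(profiles), len(accepted))

    labeled = run("label", lambda: evidence.label_pcrms(
        accepted, promoter, gene_strand if gene_strand in "+-" else "+"))
    _stage(log, "label", len(accepted), len(labeled))

    tads = None
    if cm is not None:
        prof = run("tads", lambda: chromatin_3d.insulation_profile(
            cm, config.tad_min_depth_bp, config.tad_max_depth_bp))
        tads = run("tads", lambda: chromatin_3d.call_tads(
            prof, config.tad_threshold, config.tad_delta))
    else:
        warnings.warn("no contact matrix: same_tad column undefined")
    if atac_peaks is None:
        warnings.warn("no ATAC peaks: accessible column undefined")

    rows = []
    for c in labeled:
        iv = c.profile.region.interval
        same = None
        if tads is not None:
            try:
                same = chromatin_3d.same_tad(promoter, iv, tads)
            except ValueError:
                same = None
        acc = None
        if atac_peaks is not None:
            acc = chromatin_3d.is_accessible(iv, atac_peaks)
        rows.append(
            {
                "label": c.label,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "length_bp": len(iv),
                "identity": c.profile.region.identity,
                "n_marks": c.profile.n_active_marks,
                "marks": ",".join(sorted(c.profile.marks_present)),
                "tfbs": True,
                "distance_to_promoter_bp": c.distance_to_promoter_bp,
                "same_tad": same,
                "accessible": acc,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "label", "chrom", "start", "end", "length_bp", "identity",
            "n_marks", "marks", "tfbs", "distance_to_promoter_bp",
            "same_tad", "accessible",
        ],
    )
    n_before = len(table)
    if config.require_same_tad and not table.empty:
        table = table[table["same_tad"] == True]  # noqa: E712
    if config.require_accessible and not table.empty:
        table = table[table["accessible"] == True]  # noqa: E712
    if config.require_same_tad or config.require_accessible:
        _stage(log, "tad_accessibility_filter", n_before, len(table))

    if not table.empty:
        # upstream side first, each side ordered by increasing |label|
        table = table.assign(_side=(table["label"] > 0).astype(int),
                             _rank=table["label"].abs())
        table = table.sort_values(["_side", "_rank"]).drop(columns=["_side", "_rank"])
        table = table.reset_index(drop=True)
    return ScreenReport(table=table, stage_log=log, config_echo={})
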