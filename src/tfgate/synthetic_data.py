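"""Seeded synthetic multi-omic fixtures with a ground-truth ledger.

The generator emulates the study's inputs on a toy genome: per-mark,
per-condition peak sets with planted active-promoter genes; a
negative-binomial cell-by-gene count matrix with retinal-cell-type marker
structure, a bimodal TF gene in disease-condition rods, and planted
TF+/TF- differentially expressed genes; and promoter sequences with planted
TRE full and half sites on a background scrubbed of accidental motif words.

Every output is byte-deterministic given the seed: one RNG stream per
component, derived from the config seed by fixed offsets.  The truth ledger
records planted direct targets, planted DEGs, per-cell type labels and
per-gene gate status so each pipeline stage can be scored against ground
truth.

Planted gene classes (each falsifying one clause of the downstream gate):

======================  =====================================================
class                   construction
======================  =====================================================
target                  DEG in disease rods + activation marks in OIR only
deg_both                DEG, but activation marks in both conditions
gate_oir_only           activation marks in OIR only, not a DEG
gate_normal_only        activation marks in the normal condition only
gate_repressed          all four marks (incl. H3K27me3) in OIR
gate_partial            only two of the three activation marks in OIR
======================  =====================================================
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .annotation_io import (
    CellMatrix,
    Condition,
    GeneTable,
    GenomicInterval,
    PeakSet,
    write_cell_matrix,
    write_fasta,
    write_gtf,
    write_peaks,
)
from .promoter_motif import HALF_WORDS, TRE_WORDS, MotifHit

import pandas as pd
import scipy.sparse as sp

_ROD_MARKERS = ("Rho", "Nrl", "Gnat1", "Rcvrn", "Nr2e3")
_BIPOLAR_MARKERS = ("Vsx2", "Prkca", "Grm6", "Cabp5", "Isl1")
_MUELLER_MARKERS = ("Glul", "Rlbp1", "Apoe", "Slc1a3", "Clu")

_ACTIVATION_MARKS = ("TF", "H3K27ac", "H3K4me3")
_REPRESSION_MARK = "H3K27me3"


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic bundle; ``seed`` is mandatory.

    Defaults are sized so that a desk-scale run exercises every pipeline
    stage with realistic single-cell sparsity: 400 genes, 350 cells per
    condition/timepoint, NB dispersion 2, a 4x TF+/TF- effect on planted
    DEGs, and 40% TF-positive rods in the disease condition.  The baseline
    of planted-role genes (``deg_base_mean``) is deliberately a small
    fraction of the library so that the TF+ effect perturbs total counts by
    only a few percent — as in real libraries, where differential genes are
    a sliver of total counts — keeping the compositional (library-size)
    artifact of per-cell normalization well below the fold-change threshold
    of the DEG stage.
    """

    seed: int
    n_genes: int = 400
    n_chromosomes: int = 3
    chrom_length: int = 1_500_000
    gene_min_len: int = 1_000
    gene_max_len: int = 5_000
    tss_guard: int = 3_000  # min clearance to the next gene slot (bp)
    n_cells: int = 350  # per condition x timepoint
    cell_type_proportions: tuple[tuple[str, float], ...] = (
        ("rod", 0.7),
        ("bipolar", 0.2),
        ("mueller", 0.1),
    )
    nb_mean_shape: float = 2.0
    nb_mean_scale: float = 2.0
    nb_dispersion: float = 2.0
    marker_base_mean: float = 1.0
    marker_boost: float = 20.0
    tf_gene_name: str = "Fos"
    tf_low_mean: float = 0.05
    tf_high_mean: float = 3.0
    tf_positive_fraction: float = 0.4
    n_true_targets: int = 10
    deg_fraction: float = 0.05
    deg_base_mean: float = 0.5
    target_effect: float = 4.0
    n_decoys_per_class: int = 15
    peak_width: int = 400
    peak_jitter: int = 100
    background_peak_rate: float = 5.0  # peaks per Mbp per mark per condition
    promoter_span: int = 1_100
    n_promoters: int | None = None  # default: one per direct target

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        props = dict(self.cell_type_proportions)
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("cell type proportions must sum to 1")
        for name in (
            "n_genes",
            "n_chromosomes",
            "chrom_length",
            "n_cells",
            "n_true_targets",
            "peak_width",
            "promoter_span",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        n_degs = round(self.deg_fraction * self.n_genes)
        if n_degs < self.n_true_targets:
            raise ValueError(
                "deg_fraction * n_genes must be >= n_true_targets "
                "(direct targets are a subset of the planted DEGs)"
            )

    @property
    def n_planted_degs(self) -> int:
        return round(self.deg_fraction * self.n_genes)

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class TruthLedger:
    """Ground truth planted by the generator.

    Invariants (checked by :meth:`validate`): direct targets are a subset of
    the planted DEGs, and every direct target has disease-only gate status.
    """

    direct_targets: tuple[str, ...]
    planted_degs: tuple[str, ...]
    gate_status: dict[str, dict[str, bool]]
    gene_class: dict[str, str]
    marker_map: dict[str, tuple[str, ...]]
    tf_gene_id: str
    cell_types: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        degs = set(self.planted_degs)
        for t in self.direct_targets:
            if t not in degs:
                raise AssertionError(f"direct target {t} not among planted DEGs")
            status = self.gate_status[t]
            if not (status["OIR"] and not status["normal"]):
                raise AssertionError(f"direct target {t} lacks OIR-only gate status")

    def to_json(self, dest) -> None:
        payload = {
            "direct_targets": list(self.direct_targets),
            "planted_degs": list(self.planted_degs),
            "gate_status": self.gate_status,
            "gene_class": self.gene_class,
            "marker_map": {k: list(v) for k, v in self.marker_map.items()},
            "tf_gene_id": self.tf_gene_id,
            "cell_types": self.cell_types,
        }
        from .annotation_io import _open_text

        with _open_text(dest, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, source) -> "TruthLedger":
        from .annotation_io import _open_text

        with _open_text(source) as fh:
            payload = json.load(fh)
        return cls(
            direct_targets=tuple(payload["direct_targets"]),
            planted_degs=tuple(payload["planted_degs"]),
            gate_status=payload["gate_status"],
            gene_class=payload["gene_class"],
            marker_map={k: tuple(v) for k, v in payload["marker_map"].items()},
            tf_gene_id=payload["tf_gene_id"],
            cell_types=payload["cell_types"],
        )


@dataclass
class SimBundle:
    """All generated objects of one simulation run."""

    config: SimConfig
    gene_table: GeneTable
    peaksets: list[PeakSet]
    matrix: CellMatrix
    truth: TruthLedger
    promoters: dict[str, str]
    planted_hits: dict[str, list[MotifHit]]


def _rng(config: SimConfig, component: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), component])


# ---------------------------------------------------------------------------
# roles / truth
# ---------------------------------------------------------------------------


def _gene_names(config: SimConfig) -> list[str]:
    names = list(_ROD_MARKERS + _BIPOLAR_MARKERS + _MUELLER_MARKERS)
    names.append(config.tf_gene_name)
    n_special = len(names)
    if config.n_genes < n_special + config.n_planted_degs + 4 * config.n_decoys_per_class:
        raise ValueError(
            "n_genes too small for the marker, DEG and decoy classes; need "
            f">= {n_special + config.n_planted_degs + 4 * config.n_decoys_per_class}"
        )
    names.extend(f"gene_{i:04d}" for i in range(n_special, config.n_genes))
    return names


def build_truth(config: SimConfig, gene_ids: list[str]) -> TruthLedger:
    """Assign planted roles to genes by fixed layout (no randomness needed)."""
    n_markers = 15
    marker_map = {
        "rod": tuple(gene_ids[0:5]),
        "bipolar": tuple(gene_ids[5:10]),
        "mueller": tuple(gene_ids[10:15]),
    }
    tf_gene_id = gene_ids[n_markers]
    cursor = n_markers + 1
    targets = tuple(gene_ids[cursor : cursor + config.n_true_targets])
    cursor += config.n_true_targets
    n_extra = config.n_planted_degs - config.n_true_targets
    extra_degs = tuple(gene_ids[cursor : cursor + n_extra])
    cursor += n_extra
    classes: dict[str, str] = {g: "none" for g in gene_ids}
    for g in marker_map["rod"] + marker_map["bipolar"] + marker_map["mueller"]:
        classes[g] = "marker"
    classes[tf_gene_id] = "tf"
    for g in targets:
        classes[g] = "target"
    for g in extra_degs:
        classes[g] = "deg_both"
    for cls_name in ("gate_oir_only", "gate_normal_only", "gate_repressed", "gate_partial"):
        block = gene_ids[cursor : cursor + config.n_decoys_per_class]
        cursor += config.n_decoys_per_class
        for g in block:
            classes[g] = cls_name
    gate_status = {}
    for g in gene_ids:
        cls = classes[g]
        gate_status[g] = {
            "normal": cls in ("deg_both", "gate_normal_only"),
            "OIR": cls in ("target", "deg_both", "gate_oir_only"),
        }
    truth = TruthLedger(
        direct_targets=targets,
        planted_degs=targets + extra_degs,
        gate_status=gate_status,
        gene_class=classes,
        marker_map=marker_map,
        tf_gene_id=tf_gene_id,
    )
    truth.validate()
    return truth


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def generate_annotation(
    config: SimConfig, with_genome: bool = False
) -> tuple[GeneTable, dict[str, str] | None]:
    """Place non-overlapping genes uniformly on the toy genome.

    Genes are laid out on a per-chromosome grid with random jitter, random
    strand, and random length; packing that cannot fit is an error.
    Deterministic given the config seed.
    """
    rng = _rng(config, 0)
    names = _gene_names(config)
    per_chrom = [
        config.n_genes // config.n_chromosomes
        + (1 if i < config.n_genes % config.n_chromosomes else 0)
        for i in range(config.n_chromosomes)
    ]
    gene_ids, gene_names, chroms, starts, ends, strands = [], [], [], [], [], []
    idx = 0
    for ci, n_on_chrom in enumerate(per_chrom):
        if n_on_chrom == 0:
            continue
        slot = config.chrom_length // n_on_chrom
        # the guard keeps neighboring promoter windows (and any peak planted
        # on them) from touching, so gate truth cannot leak between genes
        if slot <= config.gene_max_len + config.tss_guard:
            raise ValueError(
                f"infeasible packing: chromosome slot {slot} bp cannot hold a "
                f"gene of up to {config.gene_max_len} bp plus a "
                f"{config.tss_guard} bp guard"
            )
        chrom = f"chr{ci + 1}"
        for k in range(n_on_chrom):
            length = int(rng.integers(config.gene_min_len, config.gene_max_len + 1))
            jitter = int(rng.integers(0, slot - config.gene_max_len - config.tss_guard))
            start = k * slot + jitter
            strand = "+" if rng.random() < 0.5 else "-"
            gene_ids.append(f"g{idx:04d}")
            gene_names.append(names[idx])
            chroms.append(chrom)
            starts.append(start)
            ends.append(start + length)
            strands.append(strand)
            idx += 1
    table = GeneTable.from_fields(gene_ids, gene_names, chroms, starts, ends, strands)
    genome = None
    if with_genome:
        genome = {
            f"chr{ci + 1}": "".join(
                rng.choice(list("ACGT"), size=config.chrom_length)
            )
            for ci in range(config.n_chromosomes)
        }
    return table, genome


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

_CLASS_MARKS = {
    "target": {"OIR": _ACTIVATION_MARKS},
    "deg_both": {"normal": _ACTIVATION_MARKS, "OIR": _ACTIVATION_MARKS},
    "gate_oir_only": {"OIR": _ACTIVATION_MARKS},
    "gate_normal_only": {"normal": _ACTIVATION_MARKS},
    "gate_repressed": {"OIR": _ACTIVATION_MARKS + (_REPRESSION_MARK,)},
}


def generate_peaks(
    gene_table: GeneTable, truth: TruthLedger, config: SimConfig
) -> list[PeakSet]:
    """Plant per-class promoter peaks plus Poisson background peaks.

    Produces one :class:`PeakSet` per mark (TF, H3K27ac, H3K4me3, H3K27me3,
    IgG) and condition (normal/OIR at P14).  Planted peaks are centered on
    the TSS with small jitter so they always overlap the promoter window;
    background peaks fall uniformly at ``background_peak_rate`` per Mbp.
    IgG carries background only.
    """
    rng = _rng(config, 1)
    w = config.peak_width
    half = w // 2
    planted: dict[tuple[str, str], list[GenomicInterval]] = {}
    partial_cycle = 0
    for gene in gene_table:
        cls = truth.gene_class[gene.gene_id]
        if cls == "gate_partial":
            skip = _ACTIVATION_MARKS[partial_cycle % 3]
            partial_cycle += 1
            cond_marks = {"OIR": tuple(m for m in _ACTIVATION_MARKS if m != skip)}
        else:
            cond_marks = _CLASS_MARKS.get(cls, {})
        for group, marks in cond_marks.items():
            for mark in marks:
                jitter = int(rng.integers(-config.peak_jitter, config.peak_jitter + 1))
                center = gene.tss + jitter
                start = max(0, center - half)
                planted.setdefault((mark, group), []).append(
                    GenomicInterval(gene.interval.chrom, start, start + w, ".")
                )
    peaksets: list[PeakSet] = []
    genome_mbp = config.n_chromosomes * config.chrom_length / 1e6
    for group in ("normal", "OIR"):
        for mark in ("TF", "H3K27ac", "H3K4me3", "H3K27me3", "IgG"):
            peaks = list(planted.get((mark, group), []))
            n_bg = int(rng.poisson(config.background_peak_rate * genome_mbp))
            for _ in range(n_bg):
                chrom = f"chr{int(rng.integers(1, config.n_chromosomes + 1))}"
                start = int(rng.integers(0, config.chrom_length - w))
                peaks.append(GenomicInterval(chrom, start, start + w, "."))
            peaksets.append(
                PeakSet(mark=mark, condition=Condition(group, "P14"), peaks=tuple(peaks))
            )
    return peaksets


# ---------------------------------------------------------------------------
# scRNA counts
# ---------------------------------------------------------------------------


def generate_scrna(
    gene_table: GeneTable, truth: TruthLedger, config: SimConfig
) -> CellMatrix:
    """Negative-binomial counts with marker structure and planted DEGs.

    Cell types are drawn per cell from the configured proportions; marker
    genes are boosted ``marker_boost``-fold in their own type.  The TF gene
    is bimodal in disease-condition rods (``tf_positive_fraction`` of them at
    ``tf_high_mean``, the rest at zero) and near-silent elsewhere.  Planted
    DEG genes get a ``target_effect``-fold mean shift in TF-positive disease
    rods.  Fills ``truth.cell_types`` as a side effect.
    """
    rng = _rng(config, 2)
    gene_ids = list(gene_table.gene_ids)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    n_genes = len(gene_ids)
    base_means = rng.gamma(config.nb_mean_shape, config.nb_mean_scale, size=n_genes)
    for markers in truth.marker_map.values():
        for g in markers:
            base_means[gene_pos[g]] = config.marker_base_mean
    for g in truth.planted_degs:
        base_means[gene_pos[g]] = config.deg_base_mean
    for g, cls in truth.gene_class.items():
        if cls in ("gate_oir_only", "gate_normal_only", "gate_repressed", "gate_partial"):
            base_means[gene_pos[g]] = config.deg_base_mean
    tf_idx = gene_pos[truth.tf_gene_id]
    base_means[tf_idx] = config.tf_low_mean

    types, props = zip(*config.cell_type_proportions)
    blocks = []
    meta_rows = []
    cell_ids = []
    deg_idx = [gene_pos[g] for g in truth.planted_degs]
    for group in ("normal", "OIR"):
        for tp in ("P14", "P17"):
            n = config.n_cells
            cell_types = rng.choice(types, size=n, p=np.array(props))
            means = np.tile(base_means, (n, 1))
            for cell_type, markers in truth.marker_map.items():
                rows = cell_types == cell_type
                cols = [gene_pos[g] for g in markers]
                means[np.ix_(rows, cols)] *= config.marker_boost
            is_rod = cell_types == "rod"
            if group == "OIR":
                tf_pos = is_rod & (rng.random(n) < config.tf_positive_fraction)
                means[is_rod & ~tf_pos, tf_idx] = 0.0
                means[tf_pos, tf_idx] = config.tf_high_mean
                # TF activity on its targets is specific to the focal
                # timepoint, where the disease-state DEGs are defined
                if tp == "P14":
                    means[np.ix_(tf_pos, deg_idx)] *= config.target_effect
            r = config.nb_dispersion
            p = r / (r + means)
            counts = np.where(means > 0, rng.negative_binomial(r, np.minimum(p, 1.0)), 0)
            blocks.append(sp.csr_matrix(counts.astype(np.int64)))
            for i in range(n):
                cid = f"{group}_{tp}_c{i:04d}"
                cell_ids.append(cid)
                meta_rows.append(
                    {
                        "cell_id": cid,
                        "group": group,
                        "timepoint": tp,
                        "true_type": cell_types[i],
                    }
                )
                truth.cell_types[cid] = str(cell_types[i])
    matrix = CellMatrix(
        counts=sp.vstack(blocks, format="csr"),
        cell_ids=tuple(cell_ids),
        gene_ids=tuple(gene_ids),
        cell_meta=pd.DataFrame(meta_rows),
    )
    return matrix


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

_MAX_SCRUB_ITER = 200
_PLANT_GAP = 8  # minimal spacing between planted footprints


def _accidental_matches(
    seq: str, planted_footprints: list[tuple[int, int]], planted_full: set[int]
) -> list[tuple[int, int]]:
    """Footprints of motif words not accounted for by a planted site."""
    bad: list[tuple[int, int]] = []
    for i in range(len(seq) - 6):
        if seq[i : i + 7] in TRE_WORDS and i not in planted_full:
            bad.append((i, i + 7))
    for i in range(len(seq) - 3):
        if seq[i : i + 4] in HALF_WORDS:
            if not any(a <= i and i + 4 <= b for a, b in planted_footprints):
                bad.append((i, i + 4))
    return bad


def generate_promoters(
    truth: TruthLedger, config: SimConfig
) -> tuple[dict[str, str], dict[str, list[MotifHit]]]:
    """Promoter sequences with planted TRE full/half sites at known positions.

    The random background is scrubbed of accidental full-TRE and half-site
    words by iteratively mutating one base of each accidental match outside
    any planted footprint (a rejection loop with an iteration guard), so a
    scan recovers exactly the planted sites.
    """
    rng = _rng(config, 3)
    length = config.promoter_span
    if length < 7 + 2 * _PLANT_GAP:
        raise ValueError(f"promoter span {length} too small to plant motifs")
    n_prom = config.n_promoters
    names = [f"{g}_promoter" for g in truth.direct_targets]
    if n_prom is not None:
        if n_prom <= len(names):
            names = names[:n_prom]
        else:
            names += [f"prom_{i}" for i in range(len(names), n_prom)]
    sequences: dict[str, str] = {}
    hits: dict[str, list[MotifHit]] = {}
    for name in names:
        n_full = int(rng.integers(0, 4))
        n_half = int(rng.integers(0, 5))
        plants: list[tuple[int, str, str]] = []  # (pos, word, kind)
        occupied: list[tuple[int, int]] = []
        for kind, word_map, n_sites, wlen in (
            ("full_TRE", list(TRE_WORDS), n_full, 7),
            ("half_site", list(HALF_WORDS), n_half, 4),
        ):
            for _ in range(n_sites):
                for _try in range(100):
                    pos = int(rng.integers(0, length - wlen + 1))
                    if all(
                        pos + wlen + _PLANT_GAP <= a or b + _PLANT_GAP <= pos
                        for a, b in occupied
                    ):
                        word = word_map[int(rng.integers(0, len(word_map)))]
                        plants.append((pos, word, kind))
                        occupied.append((pos, pos + wlen))
                        break
        seq = list(rng.choice(list("ACGT"), size=length))
        for pos, word, _kind in plants:
            seq[pos : pos + len(word)] = list(word)
        planted_footprints = [(p, p + len(w)) for p, w, _ in plants]
        planted_full = {p for p, _w, k in plants if k == "full_TRE"}
        for iteration in range(_MAX_SCRUB_ITER):
            s = "".join(seq)
            bad = _accidental_matches(s, planted_footprints, planted_full)
            if not bad:
                break
            for a, b in bad:
                mutable = [
                    j
                    for j in range(a, b)
                    if not any(fa <= j < fb for fa, fb in planted_footprints)
                ]
                if not mutable:
                    continue
                j = mutable[int(rng.integers(0, len(mutable)))]
                choices = [c for c in "ACGT" if c != seq[j]]
                seq[j] = choices[int(rng.integers(0, 3))]
        else:
            raise RuntimeError(
                f"motif scrub did not converge in {_MAX_SCRUB_ITER} iterations"
            )
        final = "".join(seq)
        sequences[name] = final
        hits[name] = sorted(
            (
                MotifHit(
                    pos,
                    TRE_WORDS[word] if kind == "full_TRE" else HALF_WORDS[word],
                    kind,
                    word,
                )
                for pos, word, kind in plants
            ),
            key=lambda h: h.position,
        )
    return sequences, hits


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------


def generate_bundle(config: SimConfig) -> SimBundle:
    """Generate every fixture of one simulation run from a single config."""
    gene_table, _ = generate_annotation(config)
    gene_ids = list(gene_table.gene_ids)
    truth = build_truth(config, gene_ids)
    peaksets = generate_peaks(gene_table, truth, config)
    matrix = generate_scrna(gene_table, truth, config)
    promoters, planted_hits = generate_promoters(truth, config)
    truth.validate()
    return SimBundle(
        config=config,
        gene_table=gene_table,
        peaksets=peaksets,
        matrix=matrix,
        truth=truth,
        promoters=promoters,
        planted_hits=planted_hits,
    )


def write_bundle(bundle: SimBundle, outdir) -> dict[str, str]:
    """Write the bundle in the exact formats the readers consume.

    Returns a map from logical name to written path.  Peaks are written as
    narrowPeak under ``peaks/`` named ``{mark}_{condition}.narrowPeak``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "peaks").mkdir(exist_ok=True)
    paths: dict[str, str] = {}

    gtf = outdir / "annotation.gtf"
    write_gtf(bundle.gene_table, str(gtf))
    paths["gtf"] = str(gtf)

    for ps in bundle.peaksets:
        p = outdir / "peaks" / f"{ps.mark}_{ps.condition.label}.narrowPeak"
        write_peaks(ps, str(p), narrowpeak=True)
        paths[f"peaks:{ps.mark}:{ps.condition.label}"] = str(p)

    mtx = outdir / "matrix.mtx"
    write_cell_matrix(
        bundle.matrix,
        str(mtx),
        str(outdir / "barcodes.tsv"),
        str(outdir / "genes.tsv"),
        str(outdir / "cell_meta.tsv"),
    )
    paths["matrix"] = str(mtx)

    write_fasta(bundle.promoters, str(outdir / "promoters.fa"))
    paths["promoters"] = str(outdir / "promoters.fa")
    with open(outdir / "planted_hits.tsv", "w") as fh:
        fh.write("promoter\tposition\tstrand\tkind\tmatched_text\n")
        for name, hits in bundle.planted_hits.items():
            for h in hits:
                fh.write(
                    f"{name}\t{h.position}\t{h.strand}\t{h.kind}\t{h.matched_text}\n"
                )

    with open(outdir / "markers.yaml", "w") as fh:
        yaml.safe_dump(
            {k: list(v) for k, v in bundle.truth.marker_map.items()}, fh
        )
    paths["markers"] = str(outdir / "markers.yaml")

    bundle.truth.to_json(str(outdir / "truth.json"))
    paths["truth"] = str(outdir / "truth.json")
    return paths
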