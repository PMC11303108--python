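"""Promoter-window peak assignment and the four-mark active-promoter gate.

A gene's promoter is the closed window of ``window_halfwidth`` bp on either
side of its TSS (2w+1 bp total, left-clipped at the chromosome start).  A
gene carries a mark when at least one peak of that mark overlaps the window
by >= 1 bp.  The gate keeps genes carrying every activation mark (TF binding,
H3K27ac, H3K4me3) and lacking the repression mark (H3K27me3) — the boolean
signature of an active, TF-bound promoter.

Named gene sets are kept in a :class:`GeneSetLedger`, which supports the
condition-exclusive membership query ("in this set and no other") used to
isolate genes gated only in the disease condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from intervaltree import IntervalTree

from .annotation_io import GeneRecord, GeneTable, GenomicInterval, PeakSet


@dataclass(frozen=True)
class GateConfig:
    """Parameters of the active-promoter gate.

    window_halfwidth
        Half-width w of the promoter window in bp; the window spans
        ``[tss - w, tss + w]`` inclusive (default 1000, i.e. +/- 1.0 kb).
    activation_marks
        Marks that must all be present near the TSS.
    repression_mark
        Mark whose presence vetoes the gate.
    """

    window_halfwidth: int = 1000
    activation_marks: tuple[str, ...] = ("TF", "H3K27ac", "H3K4me3")
    repression_mark: str = "H3K27me3"

    def __post_init__(self) -> None:
        if self.window_halfwidth <= 0:
            raise ValueError("window_halfwidth must be positive")
        if self.repression_mark in self.activation_marks:
            raise ValueError("repression mark cannot also be an activation mark")


class GeneSetLedger:
    """Named gene sets over a common universe, with exclusive-set algebra."""

    def __init__(
        self,
        named_sets: Mapping[str, Iterable[str]] | None = None,
        universe: Iterable[str] | None = None,
    ):
        self._sets: dict[str, frozenset[str]] = {}
        self._universe = frozenset(universe) if universe is not None else None
        if named_sets:
            for name, members in named_sets.items():
                self.add(name, members)

    def add(self, name: str, members: Iterable[str]) -> None:
        if name in self._sets:
            raise ValueError(f"set name {name!r} already in ledger")
        members = frozenset(members)
        if self._universe is not None:
            stray = members - self._universe
            if stray:
                raise ValueError(
                    f"set {name!r} has members outside the declared universe: "
                    f"{sorted(stray)[:5]}"
                )
        self._sets[name] = members

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        if name not in self._sets:
            raise KeyError(f"no set named {name!r} in ledger")
        return self._sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __len__(self) -> int:
        return len(self._sets)

    def items(self):
        return self._sets.items()

    def to_tsv(self, dest) -> None:
        from .annotation_io import _open_text

        with _open_text(dest, "w") as fh:
            fh.write("set_name\tgene_id\n")
            for name, members in self._sets.items():
                for gid in sorted(members):
                    fh.write(f"{name}\t{gid}\n")

    @classmethod
    def from_tsv(cls, source) -> "GeneSetLedger":
        from .annotation_io import _open_text

        sets: dict[str, set[str]] = {}
        with _open_text(source) as fh:
            header = fh.readline()
            if header.rstrip("\n").split("\t") != ["set_name", "gene_id"]:
                raise ValueError("ledger TSV must have header set_name<TAB>gene_id")
            for line in fh:
                name, gid = line.rstrip("\n").split("\t")
                sets.setdefault(name, set()).add(gid)
        return cls(sets)


def promoter_window(gene: GeneRecord, config: GateConfig) -> GenomicInterval:
    """The +/- w bp promoter window around a gene's TSS, clipped at 0.

    The closed window ``[tss - w, tss + w]`` is represented half-open as
    ``[tss - w, tss + w + 1)``; only TSS placement depends on gene strand.
    """
    w = config.window_halfwidth
    start = max(0, gene.tss - w)
    return GenomicInterval(gene.interval.chrom, start, gene.tss + w + 1, ".")


def genes_with_mark(
    peaks: PeakSet, genes: GeneTable, config: GateConfig
) -> frozenset[str]:
    """Gene IDs whose promoter window overlaps >= 1 peak by >= 1 bp.

    Uses a per-chromosome interval index; contractually identical to the
    all-pairs overlap test.  Peaks on chromosomes absent from the gene table
    are ignored with a warning.
    """
    gene_chroms = genes.chroms
    trees: dict[str, IntervalTree] = {}
    stray_chroms: set[str] = set()
    for p in peaks.peaks:
        if p.chrom not in gene_chroms:
            stray_chroms.add(p.chrom)
            continue
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    if stray_chroms:
        warnings.warn(
            f"peaks on chromosome(s) {sorted(stray_chroms)} have no genes and "
            "were ignored",
            stacklevel=2,
        )
    hits: set[str] = set()
    for gene in genes:
        tree = trees.get(gene.interval.chrom)
        if tree is None:
            continue
        win = promoter_window(gene, config)
        if tree.overlaps(win.start, win.end):
            hits.add(gene.gene_id)
    return frozenset(hits)


def active_promoter_gate(
    per_mark_sets: Mapping[str, Iterable[str]], config: GateConfig
) -> frozenset[str]:
    """Genes carrying all activation marks and lacking the repression mark."""
    missing = [
        m
        for m in (*config.activation_marks, config.repression_mark)
        if m not in per_mark_sets
    ]
    if missing:
        raise KeyError(f"per-mark sets missing required mark(s): {missing}")
    result: frozenset[str] | None = None
    for mark in config.activation_marks:
        members = frozenset(per_mark_sets[mark])
        result = members if result is None else result & members
    assert result is not None
    return result - frozenset(per_mark_sets[config.repression_mark])


def exclusive_membership(ledger: GeneSetLedger, target_name: str) -> frozenset[str]:
    """Elements of the target set that belong to no other set in the ledger."""
    target = ledger[target_name]
    others: set[str] = set()
    for name, members in ledger.items():
        if name != target_name:
            others.update(members)
    return target - others


def gate_conditions(
    peaksets: Iterable[PeakSet],
    genes: GeneTable,
    config: GateConfig,
) -> tuple[GeneSetLedger, dict[str, dict[str, frozenset[str]]]]:
    """Apply the gate per condition and collect results in a ledger.

    Peak sets are grouped by condition label; each condition must supply all
    activation marks and the repression mark.  Returns the gate ledger (one
    set per condition, named by condition label) and the per-condition
    per-mark gene sets for Venn bookkeeping.
    """
    by_condition: dict[str, dict[str, frozenset[str]]] = {}
    for ps in peaksets:
        cond = ps.condition.label
        mark_sets = by_condition.setdefault(cond, {})
        members = genes_with_mark(ps, genes, config)
        if ps.mark in mark_sets:
            mark_sets[ps.mark] = mark_sets[ps.mark] | members
        else:
            mark_sets[ps.mark] = members
    ledger = GeneSetLedger(universe=genes.gene_ids)
    for cond, mark_sets in by_condition.items():
        ledger.add(cond, active_promoter_gate(mark_sets, config))
    return ledger, by_condition
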