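"""Candidate direct-target discovery: gate x expression x DEG intersection.

The discovery chain mirrors the study design: genes passing the four-mark
active-promoter gate exclusively in the focal (disease) condition, filtered
to genes expressed in the focal cells, intersected with genes differentially
expressed between TF-positive and TF-negative cells exclusively in the focal
condition.  The report stores the sets themselves (cardinalities are derived
views) plus provenance, and asserts the subset-chain invariant
``candidates <= expressed_filtered <= gate_focal_only <= gate_focal`` on
every run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation_io import CellMatrix, GeneTable, PeakSet
from .chromatin_gate import (
    GateConfig,
    GeneSetLedger,
    exclusive_membership,
    gate_conditions,
)
from .scrna_stage import (
    DEGConfig,
    classify_cells,
    diff_expr,
    expressed_genes,
    normalize_counts,
    split_by_tf,
)


@dataclass
class DiscoveryReport:
    """Sets, cardinalities, candidate table and provenance of one run."""

    focal: str
    sets: dict[str, frozenset[str]]
    candidate_table: pd.DataFrame
    provenance: dict

    def __post_init__(self) -> None:
        s = self.sets
        chain = ("candidates", "expressed_filtered", "gate_focal_only", "gate_focal")
        for inner, outer in zip(chain, chain[1:]):
            if not s[inner] <= s[outer]:
                raise AssertionError(
                    f"report invariant violated: {inner} is not a subset of {outer}"
                )
        if not s["candidates"] <= s["deg_focal_only"]:
            raise AssertionError(
                "report invariant violated: candidates not a subset of "
                "deg_focal_only"
            )

    @property
    def cardinalities(self) -> dict[str, int]:
        return {name: len(members) for name, members in self.sets.items()}

    @property
    def candidates(self) -> tuple[str, ...]:
        return tuple(self.candidate_table.index)

    def to_dict(self) -> dict:
        return {
            "focal": self.focal,
            "cardinalities": dict(sorted(self.cardinalities.items())),
            "sets": {k: sorted(v) for k, v in sorted(self.sets.items())},
            "candidates": list(self.candidates),
            "provenance": self.provenance,
        }

    def to_json(self, dest) -> None:
        from .annotation_io import _open_text

        with _open_text(dest, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")


def config_hash(*configs) -> str:
    """Stable SHA-256 digest of one or more config dataclasses."""
    import dataclasses

    payload = []
    for cfg in configs:
        if dataclasses.is_dataclass(cfg):
            payload.append(
                {k: repr(v) for k, v in sorted(dataclasses.asdict(cfg).items())}
            )
        else:
            payload.append(repr(cfg))
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()


def discover_targets(
    gate_ledger: GeneSetLedger,
    deg_ledger: GeneSetLedger,
    expressed: Iterable[str],
    focal: str,
    deg_table: pd.DataFrame | None = None,
    provenance: dict | None = None,
) -> DiscoveryReport:
    """Intersect condition-exclusive gate and DEG sets with expression.

    ``candidates = exclusive(gate, focal) & expressed & exclusive(deg, focal)``.
    The expression filter sits between the gate-exclusivity step and the DEG
    intersection; the report additionally records the cardinality of the
    alternative ordering (expression applied to the full focal gate set
    before exclusion) for comparison.  Empty focal sets yield a valid report
    with zero candidates.
    """
    if focal not in gate_ledger:
        raise KeyError(f"focal condition {focal!r} missing from gate ledger")
    if focal not in deg_ledger:
        raise KeyError(f"focal condition {focal!r} missing from DEG ledger")
    expressed = frozenset(expressed)
    gate_focal = gate_ledger[focal]
    gate_focal_only = exclusive_membership(gate_ledger, focal)
    expressed_filtered = gate_focal_only & expressed
    deg_focal_only = exclusive_membership(deg_ledger, focal)
    candidates = expressed_filtered & deg_focal_only

    sets = {
        "gate_focal": gate_focal,
        "gate_focal_only": gate_focal_only,
        "expressed_filtered": expressed_filtered,
        "deg_focal_only": deg_focal_only,
        "candidates": candidates,
    }
    for name in gate_ledger.names:
        sets[f"gate_{name}"] = gate_ledger[name]

    if deg_table is not None:
        # gene-id-sorted input + stable sort = deterministic tie-break
        table = deg_table.loc[sorted(candidates)].copy()
        table["abs_lfc"] = table["log2_fold_change"].abs()
        table = table.sort_values("abs_lfc", ascending=False, kind="stable")
        table = table.drop(columns=["abs_lfc"])
    else:
        table = pd.DataFrame(index=pd.Index(sorted(candidates), name="gene_id"))

    prov = dict(provenance or {})
    prov.setdefault("expressed_before_exclusion_cardinality", len(gate_focal & expressed))
    return DiscoveryReport(
        focal=focal, sets=sets, candidate_table=table, provenance=prov
    )


def venn_counts(ledger: GeneSetLedger) -> dict[str, int]:
    """Counts of every region of the set partition of up to 6 named sets.

    Keys are ``&``-joined sorted set names; the value counts elements that
    belong to exactly those sets and no others, so region counts sum to the
    size of the union.
    """
    names = list(ledger.names)
    if len(names) > 6:
        raise ValueError(f"venn_counts supports at most 6 sets, got {len(names)}")
    membership: dict[str, frozenset[str]] = {n: ledger[n] for n in names}
    counts: dict[str, int] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            region = frozenset.intersection(*(membership[n] for n in combo))
            for other in names:
                if other not in combo:
                    region = region - membership[other]
            counts["&".join(sorted(combo))] = len(region)
    return counts


def run_discovery(
    gene_table: GeneTable,
    peaksets: Sequence[PeakSet],
    matrix: CellMatrix,
    markers: Mapping[str, Sequence[str]],
    gate_config: GateConfig | None = None,
    deg_config: DEGConfig | None = None,
    focal: str = "OIR_P14",
    cell_type: str = "rod",
) -> tuple[DiscoveryReport, dict]:
    """Run the full discovery chain from in-memory inputs.

    Steps: per-condition gate over the peak sets; CP10K normalization;
    marker-based cell typing; subset to the requested cell type in the focal
    condition; TF+/TF- split on raw TF counts; Mann-Whitney + BH DEG test;
    expression filter; candidate intersection.  Returns the report and a
    dict of intermediates (ledgers, DEG table, labels) for inspection.
    """
    gate_config = gate_config or GateConfig()
    deg_config = deg_config or DEGConfig()
    if not deg_config.tf_gene_id:
        raise ValueError("deg_config.tf_gene_id must be set")

    gate_ledger, per_mark = gate_conditions(peaksets, gene_table, gate_config)

    norm = normalize_counts(matrix)
    labels = classify_cells(norm, markers)
    if matrix.cell_meta is None:
        raise ValueError("cell matrix has no metadata (group/timepoint needed)")
    meta = matrix.cell_meta.set_index("cell_id").loc[list(norm.cell_ids)]
    cond = meta["group"].astype(str) + "_" + meta["timepoint"].astype(str)
    focal_cells = [
        c
        for c in norm.cell_ids
        if cond.loc[c] == focal and labels.loc[c] == cell_type
    ]
    if not focal_cells:
        raise ValueError(f"no {cell_type!r} cells in focal condition {focal!r}")
    tf_pos, tf_neg = split_by_tf(matrix, focal_cells, deg_config)
    deg_table = diff_expr(norm, tf_pos, tf_neg, deg_config)
    deg_set = frozenset(deg_table.index[deg_table["significant"]])
    deg_ledger = GeneSetLedger({focal: deg_set})
    expressed = expressed_genes(matrix, focal_cells, deg_config)

    provenance = {
        "config_hash": config_hash(gate_config, deg_config),
        "n_cells_focal": len(focal_cells),
        "n_tf_positive": len(tf_pos),
        "n_tf_negative": len(tf_neg),
    }
    report = discover_targets(
        gate_ledger,
        deg_ledger,
        expressed,
        focal,
        deg_table=deg_table,
        provenance=provenance,
    )
    intermediates = {
        "gate_ledger": gate_ledger,
        "per_mark_sets": per_mark,
        "deg_table": deg_table,
        "deg_ledger": deg_ledger,
        "expressed": expressed,
        "labels": labels,
        "tf_positive": tf_pos,
        "tf_negative": tf_neg,
    }
    return report, intermediates
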