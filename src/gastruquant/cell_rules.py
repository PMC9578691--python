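"""Rule-based single-cell operations.

QC filtering on feature counts and mitochondrial fraction, lowly-expressed
gene filtering by CPM, the Hox / brain-like / spinal-cord-like neural
categorization, mutually exclusive dorsal-ventral module assignment,
differential cell-type abundance as log2 proportion ratios, and pseudo-bulk
group means.

The neural categorization applies three sequential rules: a cell expressing
at least one of a 28-gene Hox subset is Hox-positive; among Hox-negative
cells, one expressing at least five of the top-30 fore/midbrain markers and
not expressing the spinal-cord marker Fgfbp3 is brain-like; every remaining
cell is spinal-cord-like.  "Expressing" means raw count >= a configurable
threshold (default 1).

The default marker lists are editable placeholders assembled from standard
mouse gene nomenclature (the cited in vivo lists are not public as plain
text); real analyses should supply their own lists via RuleSet or a YAML
rules file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellTable",
    "RuleSet",
    "qc_filter",
    "cpm_filter",
    "classify_neural",
    "classify_dv",
    "relative_abundance",
    "pseudo_bulk",
]

MITO_PREFIX = "mt-"  # case-insensitive gene-name prefix marking mitochondrial genes

# --- default marker lists (synthetic placeholders, user-replaceable) -------

#: 28 mouse Hox genes in cluster order (subset of the 39-gene complement).
DEFAULT_HOX_GENES = [
    "Hoxa1", "Hoxa2", "Hoxa3", "Hoxa4", "Hoxa5", "Hoxa6", "Hoxa7",
    "Hoxa9", "Hoxa10", "Hoxa11", "Hoxb1", "Hoxb2", "Hoxb3", "Hoxb4",
    "Hoxb5", "Hoxb6", "Hoxb7", "Hoxb8", "Hoxb9", "Hoxc4", "Hoxc5",
    "Hoxc6", "Hoxc8", "Hoxc9", "Hoxd1", "Hoxd3", "Hoxd4", "Hoxd8",
]

#: 30 canonical mouse fore/midbrain transcription-factor markers.
DEFAULT_BRAIN_MARKERS = [
    "Otx2", "Otx1", "Six3", "Six6", "Foxg1", "Emx1", "Emx2", "En1",
    "En2", "Pax6", "Pax2", "Lhx2", "Lhx5", "Fezf1", "Fezf2", "Rax",
    "Hesx1", "Vax1", "Dlx1", "Dlx2", "Nkx2-1", "Barhl2", "Dmbx1",
    "Wnt8b", "Fgf8", "Fgf17", "Sfrp1", "Sfrp2", "Gbx2", "Irx3",
]

#: Dorsal / midline / ventral neural-tube module genes (three each).
DEFAULT_DV_MODULES = {
    "dorsal": ["Pax3", "Pax7", "Msx1"],
    "midline": ["Shh", "Foxa2", "Ntn1"],
    "ventral": ["Nkx2-2", "Olig2", "Nkx6-1"],
}


@dataclass
class RuleSet:
    """Marker-gene modules and thresholds driving cell categorization."""

    hox_genes: list[str] = field(default_factory=lambda: list(DEFAULT_HOX_GENES))
    brain_markers: list[str] = field(default_factory=lambda: list(DEFAULT_BRAIN_MARKERS))
    brain_min_markers: int = 5
    spinal_exclusion_gene: str = "Fgfbp3"
    dv_modules: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_DV_MODULES.items()}
    )
    expressed_threshold: int = 1  # count >= threshold means "expressed"

    def __post_init__(self) -> None:
        if self.brain_min_markers > len(self.brain_markers):
            raise ValueError("brain_min_markers exceeds the brain marker list length")
        flat = [g for genes in self.dv_modules.values() for g in genes]
        if len(flat) != len(set(flat)):
            raise ValueError("dorsal/midline/ventral gene lists overlap")

    @classmethod
    def from_yaml(cls, path) -> "RuleSet":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "hox_genes": list(self.hox_genes),
            "brain_markers": list(self.brain_markers),
            "brain_min_markers": self.brain_min_markers,
            "spinal_exclusion_gene": self.spinal_exclusion_gene,
            "dv_modules": {k: list(v) for k, v in self.dv_modules.items()},
            "expressed_threshold": self.expressed_threshold,
        }


class CellTable:
    """Cells × genes count matrix with per-cell metadata.

    ``cell_meta`` always carries ``n_features`` (genes with count > 0),
    ``total_counts`` and ``mito_fraction`` (fraction of counts on genes
    whose name starts with "mt-", case-insensitive); a ``condition`` column
    and an optional ``annotation`` column hold experimental labels.
    """

    def __init__(
        self,
        counts: np.ndarray,
        gene_names: Sequence[str],
        cell_ids: Sequence[str],
        cell_meta: pd.DataFrame | None = None,
    ) -> None:
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValueError("counts must be 2-D (cells x genes)")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if counts.shape != (len(cell_ids), len(gene_names)):
            raise ValueError(
                f"counts shape {counts.shape} inconsistent with "
                f"{len(cell_ids)} cells x {len(gene_names)} genes"
            )
        if len(set(gene_names)) != len(gene_names):
            raise ValueError("gene_names must be unique")
        self.counts = counts
        self.gene_names = list(gene_names)
        self.cell_ids = list(cell_ids)
        meta = pd.DataFrame(index=pd.Index(self.cell_ids)) if cell_meta is None else cell_meta.copy()
        if not meta.index.equals(pd.Index(self.cell_ids)):
            meta = meta.reindex(self.cell_ids)
        self.cell_meta = meta
        self._compute_qc_stats()

    # -- derived stats ------------------------------------------------------
    def _compute_qc_stats(self) -> None:
        total = self.counts.sum(axis=1)
        mito = np.array(
            [g.lower().startswith(MITO_PREFIX) for g in self.gene_names], dtype=bool
        )
        mito_counts = self.counts[:, mito].sum(axis=1) if mito.any() else np.zeros_like(total)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, mito_counts / np.maximum(total, 1), 0.0)
        self.cell_meta["n_features"] = (self.counts > 0).sum(axis=1)
        self.cell_meta["total_counts"] = total
        self.cell_meta["mito_fraction"] = frac

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, genes: Sequence[str], context: str = "rule") -> np.ndarray:
        missing = [g for g in genes if g not in self._gene_lookup]
        if missing:
            raise KeyError(
                f"{context} references genes absent from the table: {missing}"
            )
        return np.array([self._gene_lookup[g] for g in genes], dtype=int)

    @property
    def _gene_lookup(self) -> dict[str, int]:
        lut = getattr(self, "_lut", None)
        if lut is None or len(lut) != len(self.gene_names):
            lut = {g: j for j, g in enumerate(self.gene_names)}
            self._lut = lut
        return lut

    def subset_cells(self, keep: np.ndarray) -> "CellTable":
        keep = np.asarray(keep)
        ids = [self.cell_ids[i] for i in np.flatnonzero(keep)] if keep.dtype == bool else [
            self.cell_ids[i] for i in keep
        ]
        return CellTable(
            counts=self.counts[keep],
            gene_names=self.gene_names,
            cell_ids=ids,
            cell_meta=self.cell_meta.loc[ids].drop(
                columns=["n_features", "total_counts", "mito_fraction"], errors="ignore"
            ),
        )

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (cells x genes)."""
        import anndata as ad

        return ad.AnnData(
            X=self.counts.astype(np.float32),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=pd.Index(self.gene_names, name="gene")),
        )


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def qc_filter(
    table: CellTable,
    min_features: int = 200,
    max_features: int = 2500,
    max_mito: float = 0.05,
) -> tuple[CellTable, pd.DataFrame]:
    """Drop low-quality cells on feature count and mitochondrial fraction.

    Keeps cells with ``min_features <= n_features <= max_features`` and
    ``mito_fraction <= max_mito`` (bounds inclusive: the removal rules are
    "fewer than", "more than" and "above").  Returns the filtered table and
    a per-cell keep/drop report with the offending rule(s).
    """
    if table.n_cells == 0:
        raise ValueError("empty cell table")
    nf = table.cell_meta["n_features"].to_numpy()
    mf = table.cell_meta["mito_fraction"].to_numpy()
    low = nf < min_features
    high = nf > max_features
    mito = mf > max_mito
    keep = ~(low | high | mito)
    report = pd.DataFrame(
        {
            "kept": keep,
            "too_few_features": low,
            "too_many_features": high,
            "high_mito": mito,
        },
        index=pd.Index(table.cell_ids),
    )
    return table.subset_cells(keep), report


def cpm_filter(
    counts: pd.DataFrame | np.ndarray,
    min_cpm: float = 0.4,
    min_samples: int = 2,
    gene_names: Sequence[str] | None = None,
) -> list:
    """Keep genes with CPM strictly above ``min_cpm`` in >= ``min_samples`` samples.

    ``counts`` is samples × genes (the bulk orientation).  CPM is
    count / sample total × 1e6.  A gene at exactly ``min_cpm`` everywhere is
    dropped (strict inequality).  Returns the kept gene names (or column
    indices for a bare array without names).
    """
    if isinstance(counts, pd.DataFrame):
        names = list(counts.columns)
        mat = counts.to_numpy(dtype=float)
        sample_ids = list(counts.index)
    else:
        mat = np.asarray(counts, dtype=float)
        names = list(gene_names) if gene_names is not None else list(range(mat.shape[1]))
        sample_ids = list(range(mat.shape[0]))
    totals = mat.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"sample(s) with zero total counts: {[sample_ids[i] for i in zero]}")
    cpm = mat / totals[:, None] * 1e6
    keep = (cpm > min_cpm).sum(axis=0) >= min_samples
    return [names[j] for j in np.flatnonzero(keep)]


# ---------------------------------------------------------------------------
# categorization
# ---------------------------------------------------------------------------

def classify_neural(table: CellTable, rules: RuleSet) -> pd.Series:
    """Hox-positive / brain-like / spinal-cord-like label per cell.

    Precedence: (1) any Hox gene expressed → ``hox_positive``; (2) else at
    least ``brain_min_markers`` brain markers expressed and the spinal
    exclusion gene (Fgfbp3) not expressed → ``brain_like``; (3) all
    remaining cells → ``spinal_like``.  Every cell receives exactly one
    label.
    """
    thr = rules.expressed_threshold
    expressed = table.counts >= thr
    hox_idx = table.gene_index(rules.hox_genes, "hox_genes")
    brain_idx = table.gene_index(rules.brain_markers, "brain_markers")
    excl_idx = table.gene_index([rules.spinal_exclusion_gene], "spinal_exclusion_gene")[0]

    any_hox = expressed[:, hox_idx].any(axis=1)
    n_brain = expressed[:, brain_idx].sum(axis=1)
    excl_on = expressed[:, excl_idx]

    labels = np.full(table.n_cells, "spinal_like", dtype=object)
    labels[(~any_hox) & (n_brain >= rules.brain_min_markers) & (~excl_on)] = "brain_like"
    labels[any_hox] = "hox_positive"
    return pd.Series(labels, index=pd.Index(table.cell_ids), name="neural_class")


def classify_dv(table: CellTable, rules: RuleSet) -> pd.Series:
    """Mutually exclusive dorsal / midline / ventral module assignment.

    A cell belongs to a module iff it expresses at least one of that
    module's genes and none of the other modules' genes; cells matching
    zero or several modules are ``unassigned``.
    """
    if not rules.dv_modules:
        raise ValueError("dv_modules is empty")
    thr = rules.expressed_threshold
    expressed = table.counts >= thr
    module_hits = {}
    for name, genes in rules.dv_modules.items():
        idx = table.gene_index(genes, f"dv_modules[{name}]")
        module_hits[name] = expressed[:, idx].any(axis=1)
    hits = pd.DataFrame(module_hits, index=pd.Index(table.cell_ids))
    n_hit = hits.sum(axis=1)
    labels = pd.Series("unassigned", index=hits.index, name="dv_class", dtype=object)
    single = n_hit == 1
    labels[single] = hits.loc[single].idxmax(axis=1)
    return labels


def dv_assigned_fraction(labels: pd.Series) -> float:
    """Fraction of cells surviving the DV categorization (not unassigned)."""
    return float((labels != "unassigned").mean())


# ---------------------------------------------------------------------------
# abundance and pseudo-bulk
# ---------------------------------------------------------------------------

def relative_abundance(
    annotations: pd.Series,
    conditions: pd.Series,
    reference_condition: str,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Per-state log2 ratio of cell-state proportions versus a reference.

    Proportions are state cells / condition cells within each condition.
    States with fewer than ``min_cells`` cells summed across all conditions
    are excluded.  A state absent on exactly one side yields ±inf, kept and
    flagged in the ``infinite`` column rather than dropped.
    """
    annotations = pd.Series(annotations)
    conditions = pd.Series(conditions)
    if len(annotations) != len(conditions):
        raise ValueError("annotations and conditions differ in length")
    if reference_condition not in set(conditions):
        raise ValueError(f"reference condition {reference_condition!r} has no cells")

    df = pd.DataFrame({"state": annotations.to_numpy(), "condition": conditions.to_numpy()})
    totals = df.groupby("state").size()
    states = totals[totals >= min_cells].index
    cond_sizes = df.groupby("condition").size()

    counts = (
        df.groupby(["state", "condition"]).size().unstack(fill_value=0).reindex(states)
    )
    props = counts.div(cond_sizes, axis=1)

    out_rows = []
    for cond in cond_sizes.index:
        if cond == reference_condition:
            continue
        with np.errstate(divide="ignore"):
            ratio = np.log2(props[cond].to_numpy() / props[reference_condition].to_numpy())
        for state, lr, pc, pr in zip(
            states, ratio, props[cond].to_numpy(), props[reference_condition].to_numpy()
        ):
            out_rows.append(
                {
                    "state": state,
                    "condition": cond,
                    "proportion": pc,
                    "reference_proportion": pr,
                    "log2_ratio": lr,
                    "infinite": bool(np.isinf(lr)),
                }
            )
    return pd.DataFrame(out_rows)


def pseudo_bulk(
    table: CellTable,
    group_keys: Sequence[str],
    normalization: str = "lognorm",
    scale_total: float = 1e4,
) -> pd.DataFrame:
    """Mean expression per group per gene (groups × genes).

    ``normalization='lognorm'`` scales each cell to ``scale_total`` counts
    and applies log1p before averaging, mirroring the upstream single-cell
    normalization; ``'counts'`` averages raw counts.
    """
    for key in group_keys:
        if key not in table.cell_meta.columns:
            raise KeyError(f"group key {key!r} not in cell_meta")
    if table.n_cells == 0:
        raise ValueError("empty cell table")
    if normalization == "lognorm":
        totals = np.maximum(table.counts.sum(axis=1, keepdims=True), 1)
        X = np.log1p(table.counts / totals * scale_total)
    elif normalization == "counts":
        X = table.counts.astype(float)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    expr = pd.DataFrame(X, index=pd.Index(table.cell_ids), columns=table.gene_names)
    groups = table.cell_meta.loc[expr.index, list(group_keys)]
    return expr.groupby([groups[k] for k in group_keys]).mean()
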