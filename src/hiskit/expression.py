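"""HIS scoring of bulk expression data.

A tumor's Heterogeneity of Immune checkpoint Signature (HIS) is read off a
panel of immune checkpoint genes: for each gene the fold change (FC) of its
mean FPKM in a comparison group (e.g. baseline large tumors) over a baseline
group (e.g. baseline small tumors) is computed, and the tumor state is called

* HIS-high  when >= `high_min` (default 10) panel genes have FC >= `fc_cut`
  (default 2.0),
* HIS-low   when <= `low_max` (default 5) genes do,
* indeterminate for counts in the gap between the two thresholds.

FPKM (fragments per kilobase of exon per million mapped fragments) is
length- and depth-normalized, so FPKM means are comparable across samples.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenePanel",
    "ExpressionMatrix",
    "FoldChangeProfile",
    "HISCall",
    "HISLabel",
    "DEFAULT_PANEL",
    "compute_group_means",
    "compute_fold_changes",
    "classify_his",
    "count_directional",
    "standardize_matrix",
]


@dataclass(frozen=True)
class GenePanel:
    """An ordered, unique set of checkpoint gene identifiers."""

    gene_ids: tuple[str, ...]
    display_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.gene_ids) == 0:
            raise ValueError("gene panel must be non-empty")
        if len(set(g.lower() for g in self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene panel identifiers must be unique (case-insensitive)")
        if self.display_names is not None and len(self.display_names) != len(self.gene_ids):
            raise ValueError("display_names length must match gene_ids")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __iter__(self):
        return iter(self.gene_ids)

    def subset(self, gene_ids) -> "GenePanel":
        keep = [g.lower() for g in gene_ids]
        idx = [i for i, g in enumerate(self.gene_ids) if g.lower() in keep]
        return GenePanel(
            tuple(self.gene_ids[i] for i in idx),
            None if self.display_names is None else tuple(self.display_names[i] for i in idx),
        )


# Default 34-gene immune checkpoint panel (mouse gene symbols). The first
# eleven are checkpoints named in the analyses this package was built for
# (PD1=Pdcd1, PD-L1=Cd274, TIM3=Havcr2, CD73=Nt5e); the remainder are
# commonly studied co-inhibitory/checkpoint genes completing the panel.
# Any study should substitute its own panel; every function takes one.
DEFAULT_PANEL = GenePanel(
    gene_ids=(
        "Pdcd1", "Cd274", "Ctla4", "Lag3", "Havcr2", "Tigit",
        "Cd200", "Pvrig", "Nt5e", "Tdo2", "Cd33",
        "Vsir", "Btla", "Cd276", "Vtcn1", "Ido1", "Ido2", "Lgals9",
        "Pdcd1lg2", "Hhla2", "Cd160", "Cd96", "Adora2a", "Entpd1",
        "Cd47", "Sirpa", "Ceacam1", "Fgl1", "Nectin2", "Pvr",
        "Cd200r1", "Klrb1c", "Cd244a", "Arg1",
    ),
)
assert len(DEFAULT_PANEL) == 34


@dataclass
class ExpressionMatrix:
    """Nonnegative FPKM values over a gene panel x labeled samples.

    ``values`` is genes x samples, row order following ``panel``.
    """

    panel: GenePanel
    sample_ids: tuple[str, ...]
    group_labels: dict[str, str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.panel), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.panel)} panel genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("FPKM values must be >= 0")
        missing = [s for s in self.sample_ids if s not in self.group_labels]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")

    @property
    def groups(self) -> tuple[str, ...]:
        seen: list[str] = []
        for s in self.sample_ids:
            g = self.group_labels[s]
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_labels[s] == group]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.panel.gene_ids),
                            columns=list(self.sample_ids))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, group_labels: dict[str, str],
                   panel: GenePanel | None = None) -> "ExpressionMatrix":
        if panel is None:
            panel = GenePanel(tuple(str(g) for g in frame.index))
        return cls(panel=panel, sample_ids=tuple(str(c) for c in frame.columns),
                   group_labels=dict(group_labels), values=frame.to_numpy(dtype=float))


@dataclass
class FoldChangeProfile:
    """Per-gene fold changes of comparison-group over baseline-group mean FPKM.

    fc[g] = (mean_comparison[g] + pseudocount) / (mean_baseline[g] + pseudocount)
    """

    gene_ids: tuple[str, ...]
    mean_baseline: np.ndarray
    mean_comparison: np.ndarray
    fc: np.ndarray
    pseudocount: float
    baseline_group: str = ""
    comparison_group: str = ""

    def __len__(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_baseline": self.mean_baseline,
                "mean_comparison": self.mean_comparison,
                "fc": self.fc,
            },
            index=list(self.gene_ids),
        )


class HISLabel(str, enum.Enum):
    HIS_HIGH = "HIS_HIGH"
    HIS_LOW = "HIS_LOW"
    INDETERMINATE = "INDETERMINATE"


@dataclass(frozen=True)
class HISCall:
    """Tri-state HIS classification with the gene count behind it."""

    label: HISLabel
    n_genes_fc_ge_cut: int
    fc_cut: float = 2.0
    high_min: int = 10
    low_max: int = 5


def compute_group_means(expr: ExpressionMatrix, group: str) -> np.ndarray:
    """Arithmetic mean FPKM per panel gene over the samples of ``group``."""
    samples = expr.samples_in(group)
    if not samples:
        raise ValueError(
            f"unknown or empty group {group!r}; available groups: {list(expr.groups)}"
        )
    cols = [expr.sample_ids.index(s) for s in samples]
    return expr.values[:, cols].mean(axis=1)


def compute_fold_changes(
    expr: ExpressionMatrix,
    baseline_group: str,
    comparison_group: str,
    pseudocount: float = 0.01,
) -> FoldChangeProfile:
    """Per-gene FC of comparison-group mean FPKM over baseline-group mean.

    ``pseudocount`` (FPKM) is added to both means so genes silent in the
    baseline group still yield a finite ratio; pass 0 to forbid this, in
    which case a zero baseline mean raises.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    mean_base = compute_group_means(expr, baseline_group)
    mean_comp = compute_group_means(expr, comparison_group)
    denom = mean_base + pseudocount
    if np.any(denom == 0):
        bad = [g for g, d in zip(expr.panel.gene_ids, denom) if d == 0]
        raise ZeroDivisionError(
            f"baseline mean + pseudocount is zero for genes {bad}; "
            "use a positive pseudocount to keep fold changes finite"
        )
    fc = (mean_comp + pseudocount) / denom
    return FoldChangeProfile(
        gene_ids=expr.panel.gene_ids,
        mean_baseline=mean_base,
        mean_comparison=mean_comp,
        fc=fc,
        pseudocount=pseudocount,
        baseline_group=baseline_group,
        comparison_group=comparison_group,
    )


def classify_his(
    profile: FoldChangeProfile,
    fc_cut: float = 2.0,
    high_min: int = 10,
    low_max: int = 5,
) -> HISCall:
    """Call HIS-high / HIS-low / indeterminate from a fold-change profile.

    The count uses the inclusive rule FC >= ``fc_cut``. Counts strictly
    between ``low_max`` and ``high_min`` are a gap in the published
    dichotomy; they are returned as INDETERMINATE rather than forced to
    either side.
    """
    if len(profile) == 0:
        raise ValueError("fold-change profile is empty")
    if not low_max < high_min:
        raise ValueError("low_max must be < high_min")
    n = int(np.sum(profile.fc >= fc_cut))
    if n >= high_min:
        label = HISLabel.HIS_HIGH
    elif n <= low_max:
        label = HISLabel.HIS_LOW
    else:
        label = HISLabel.INDETERMINATE
    return HISCall(label=label, n_genes_fc_ge_cut=n, fc_cut=fc_cut,
                   high_min=high_min, low_max=low_max)


def count_directional(profile: FoldChangeProfile, up_cut: float = 2.0) -> tuple[int, int]:
    """Count genes up- (FC >= up_cut) and down-regulated (FC <= 1/up_cut).

    The down rule is the reciprocal of the up rule, so swapping the two
    groups swaps the counts (at pseudocount 0). Genes with FC strictly
    between 1/up_cut and up_cut belong to neither count.
    """
    if not up_cut > 1:
        raise ValueError("up_cut must be > 1")
    n_up = int(np.sum(profile.fc >= up_cut))
    n_down = int(np.sum(profile.fc <= 1.0 / up_cut))
    return n_up, n_down


def standardize_matrix(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene z-scores of the FPKM matrix, for sample-distribution plots.

    Each gene row is centered and scaled by its sample (ddof=1) standard
    deviation; constant rows map to all-zeros. Returns a DataFrame
    (genes x samples) since z-scores are no longer FPKM.
    """
    if len(expr.sample_ids) < 2:
        raise ValueError("standardization requires >= 2 samples")
    v = expr.values
    mean = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (v - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return pd.DataFrame(z, index=list(expr.panel.gene_ids), columns=list(expr.sample_ids))
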