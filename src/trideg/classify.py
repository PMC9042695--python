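"""Perturbation classification for the three-contrast IFN-λ3 / IFN-λ4 design.

Within one cell type, every gene carries results for three contrasts:

* ``L3vNT`` — IFN-λ3-treated vs. untreated (set A of the three-set Venn),
* ``L4vNT`` — IFN-λ4-treated vs. untreated (set B),
* ``L4vL3`` — IFN-λ4-treated vs. IFN-λ3-treated (set C),

where set membership means the gene passed the DEG rule (|FC| > fc_thresh
and p < p_thresh) in that contrast.  On top of the raw significance pattern,
each interferon's effect on a gene is graded into a qualitative *tier*
(strong / moderate / weak / null) and a perturbation verdict is derived from
the gene's own tier together with the *other* interferon's tier and relative
direction.  The point of the scheme is to rescue genes whose per-IFN effect
is individually sub-threshold but whose λ4-vs-λ3 contrast shows they are
genuinely driven apart (or together) by the two ligands.

Decision rules (X is either interferon, Y the other; "same"/"opposite"
compare the signs of the mean fold changes vs. NT):

==========  =========================================  ==============
tier_X      condition on Y                             perturbed_X
==========  =========================================  ==============
strong      —                                          True
moderate    —                                          True
weak        Y moderate, same direction                 True
weak        Y weak, opposite direction                 True
weak        Y strong (either direction)                False
weak        Y moderate, opposite direction             False
weak        Y weak, same direction / Y null            False
null        —                                          False
==========  =========================================  ==============

A gene perturbed by both IFNs in opposite directions is *reciprocally
regulated*; perturbed by both in the same direction is *same_direction*;
perturbed by exactly one is unique to that interferon; perturbed by
neither is *unperturbed_both*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TierThresholds",
    "GeneClass",
    "ClassificationSummary",
    "assign_tier",
    "classify_gene",
    "classify_table",
    "venn_region",
    "two_set_venn",
    "summarize",
    "REGIONS",
    "TIERS",
    "CATEGORIES",
]

#: The seven nonempty regions of a three-set Venn diagram plus "none".
REGIONS = ("A_only", "B_only", "C_only", "AB", "AC", "BC", "ABC", "none")

TIERS = ("strong", "moderate", "weak", "null")

CATEGORIES = (
    "reciprocal",
    "same_direction",
    "l4_unique",
    "l3_unique",
    "unperturbed_both",
    "other",
)

#: Columns a per-cell-type classification input table must provide:
#: signed fold change and p-value for each of the three contrasts.
TRIPLET_COLUMNS = (
    "signed_fc_l3",
    "p_l3",
    "signed_fc_l4",
    "p_l4",
    "signed_fc_l4vl3",
    "p_l4vl3",
)


@dataclass(frozen=True)
class TierThresholds:
    """Numeric boundaries of the qualitative effect tiers.

    fc_thresh / p_thresh are the DEG rule; strong_fc separates strong from
    moderate significant effects; weak_floor_fc is the minimum fold change
    for a sub-significant effect to count as weak rather than null.  All
    fold-change thresholds are on the signed-FC magnitude scale (>= 1).
    """

    fc_thresh: float = 1.5
    p_thresh: float = 0.05
    strong_fc: float = 4.0
    weak_floor_fc: float = 1.1

    def __post_init__(self) -> None:
        if not (1.0 < self.weak_floor_fc < self.fc_thresh < self.strong_fc):
            raise ValueError(
                "tier thresholds must satisfy 1 < weak_floor_fc < fc_thresh "
                f"< strong_fc, got {self}"
            )
        if not (0.0 < self.p_thresh <= 1.0):
            raise ValueError(f"p_thresh must be in (0, 1], got {self.p_thresh}")


@dataclass(frozen=True)
class GeneClass:
    """Per-gene classification result within one cell type."""

    tier_l3: str
    tier_l4: str
    dir_l3: int
    dir_l4: int
    venn_region: str
    perturbed_l3: bool
    perturbed_l4: bool
    category: str


def _is_sig(signed_fc: float, p: float, thr: TierThresholds) -> bool:
    """DEG rule: strictly more than fc_thresh-fold change and p below p_thresh."""
    return abs(signed_fc) > thr.fc_thresh and p < thr.p_thresh


def assign_tier(
    signed_fc_vs_nt: float,
    p_vs_nt: float,
    sig_in_l4vl3: bool,
    thresholds: TierThresholds = TierThresholds(),
) -> str:
    """Grade one interferon's effect on a gene.

    strong / moderate require significance vs. NT and are split at
    ``strong_fc``; a sub-significant effect is weak if its magnitude clears
    ``weak_floor_fc`` *or* the gene is significant in the λ4-vs-λ3
    contrast (evidence that the two IFNs pull it apart); otherwise null.
    """
    mag = abs(signed_fc_vs_nt)
    if _is_sig(signed_fc_vs_nt, p_vs_nt, thresholds):
        return "strong" if mag >= thresholds.strong_fc else "moderate"
    if mag >= thresholds.weak_floor_fc or sig_in_l4vl3:
        return "weak"
    return "null"


def _perturbed(tier_x: str, tier_y: str, same_dir: bool, opposite_dir: bool) -> bool:
    if tier_x in ("strong", "moderate"):
        return True
    if tier_x == "null":
        return False
    # weak: rescued only by a moderate same-direction or weak opposite-direction partner
    if tier_y == "moderate" and same_dir:
        return True
    if tier_y == "weak" and opposite_dir:
        return True
    return False


def venn_region(sig_a: bool, sig_b: bool, sig_c: bool) -> str:
    """Map a significance pattern over (L3vNT, L4vNT, L4vL3) to its Venn region."""
    key = (bool(sig_a), bool(sig_b), bool(sig_c))
    return {
        (True, False, False): "A_only",
        (False, True, False): "B_only",
        (False, False, True): "C_only",
        (True, True, False): "AB",
        (True, False, True): "AC",
        (False, True, True): "BC",
        (True, True, True): "ABC",
        (False, False, False): "none",
    }[key]


def classify_gene(
    signed_fc_l3: float,
    p_l3: float,
    signed_fc_l4: float,
    p_l4: float,
    signed_fc_l4vl3: float,
    p_l4vl3: float,
    thresholds: TierThresholds = TierThresholds(),
) -> GeneClass:
    """Classify one gene from its three-contrast results in one cell type."""
    for name, val in (("p_l3", p_l3), ("p_l4", p_l4), ("p_l4vl3", p_l4vl3)):
        if not np.isfinite(val):
            raise ValueError(f"missing contrast value {name}; all three contrasts are required")

    thr = thresholds
    sig_a = _is_sig(signed_fc_l3, p_l3, thr)
    sig_b = _is_sig(signed_fc_l4, p_l4, thr)
    sig_c = _is_sig(signed_fc_l4vl3, p_l4vl3, thr)

    tier3 = assign_tier(signed_fc_l3, p_l3, sig_c, thr)
    tier4 = assign_tier(signed_fc_l4, p_l4, sig_c, thr)

    # direction = sign of the mean FC vs NT on the log scale: a signed FC of
    # +1 or -1 is "no change", so it carries direction 0, not its own sign
    def _dir(fc: float, tier: str) -> int:
        if tier == "null" or abs(fc) <= 1.0:
            return 0
        return int(np.sign(fc))

    dir3 = _dir(signed_fc_l3, tier3)
    dir4 = _dir(signed_fc_l4, tier4)
    if dir3 == 0:
        tier3 = "null"  # degenerate FC exactly 1; no direction, no effect
    if dir4 == 0:
        tier4 = "null"

    same = dir3 != 0 and dir3 == dir4
    opp = dir3 != 0 and dir3 == -dir4

    pert3 = _perturbed(tier3, tier4, same, opp)
    pert4 = _perturbed(tier4, tier3, same, opp)

    if pert3 and pert4:
        category = "reciprocal" if opp else ("same_direction" if same else "other")
    elif pert4:
        category = "l4_unique"
    elif pert3:
        category = "l3_unique"
    else:
        category = "unperturbed_both"

    return GeneClass(
        tier_l3=tier3,
        tier_l4=tier4,
        dir_l3=dir3,
        dir_l4=dir4,
        venn_region=venn_region(sig_a, sig_b, sig_c),
        perturbed_l3=pert3,
        perturbed_l4=pert4,
        category=category,
    )


def classify_table(
    triplet: pd.DataFrame, thresholds: TierThresholds = TierThresholds()
) -> pd.DataFrame:
    """Classify every gene of a per-cell-type triplet table.

    ``triplet`` must carry :data:`TRIPLET_COLUMNS`; its index is the gene id.
    Returns a DataFrame with one row per gene: tiers, directions, Venn
    region, perturbation verdicts, category, and the three significance
    flags (sig_l3, sig_l4, sig_l4vl3).
    """
    missing = [c for c in TRIPLET_COLUMNS if c not in triplet.columns]
    if missing:
        raise ValueError(f"triplet table is missing columns: {missing}")

    records = []
    for gene, row in triplet.iterrows():
        gc = classify_gene(
            row["signed_fc_l3"],
            row["p_l3"],
            row["signed_fc_l4"],
            row["p_l4"],
            row["signed_fc_l4vl3"],
            row["p_l4vl3"],
            thresholds,
        )
        records.append(
            {
                "gene": gene,
                "tier_l3": gc.tier_l3,
                "tier_l4": gc.tier_l4,
                "dir_l3": gc.dir_l3,
                "dir_l4": gc.dir_l4,
                "venn_region": gc.venn_region,
                "perturbed_l3": gc.perturbed_l3,
                "perturbed_l4": gc.perturbed_l4,
                "category": gc.category,
                "sig_l3": _is_sig(row["signed_fc_l3"], row["p_l3"], thresholds),
                "sig_l4": _is_sig(row["signed_fc_l4"], row["p_l4"], thresholds),
                "sig_l4vl3": _is_sig(row["signed_fc_l4vl3"], row["p_l4vl3"], thresholds),
            }
        )
    out = pd.DataFrame.from_records(records)
    if len(out):
        out = out.set_index("gene")
    else:
        out = pd.DataFrame(
            columns=[
                "tier_l3", "tier_l4", "dir_l3", "dir_l4", "venn_region",
                "perturbed_l3", "perturbed_l4", "category",
                "sig_l3", "sig_l4", "sig_l4vl3",
            ]
        )
    return out


def two_set_venn(deg_a: Iterable[str], deg_b: Iterable[str]) -> tuple[set, set, set]:
    """Disjoint (unique_a, unique_b, common) partition of two DEG sets."""
    a, b = set(deg_a), set(deg_b)
    return a - b, b - a, a & b


@dataclass
class CellTypeSummary:
    """Classification counts for one cell type."""

    region_counts: dict[str, int]
    category_counts: dict[str, int]
    n_significant: int
    unperturbed_by_l4: int
    unperturbed_by_l3: int
    reciprocal: int
    c_only_reciprocal: int
    c_only_reciprocal_down_l3_up_l4: int
    c_only_reciprocal_up_l3_down_l4: int
    l4_sig_unique: int
    l4_sig_unique_same_direction: int
    same_direction_weak_l4: int


@dataclass
class ClassificationSummary:
    """Venn-region and perturbation-category accounting across cell types.

    ``lambda4_unique_total`` counts genes *significantly* affected by IFN-λ4
    vs. NT but not by IFN-λ3 vs. NT (the significance-unique group); the
    perturbation-based category ``l4_unique`` is tallied separately inside
    each cell type's category_counts.
    """

    per_cell_type: dict[str, CellTypeSummary] = field(default_factory=dict)

    @property
    def reciprocal_total(self) -> int:
        return sum(s.reciprocal for s in self.per_cell_type.values())

    @property
    def lambda4_unique_total(self) -> int:
        return sum(s.l4_sig_unique for s in self.per_cell_type.values())

    @property
    def lambda4_unique_same_direction_total(self) -> int:
        return sum(s.l4_sig_unique_same_direction for s in self.per_cell_type.values())

    def to_dict(self) -> dict:
        out: dict = {"per_cell_type": {}}
        for ct, s in sorted(self.per_cell_type.items()):
            out["per_cell_type"][ct] = {
                "region_counts": dict(s.region_counts),
                "category_counts": dict(s.category_counts),
                "n_significant": s.n_significant,
                "unperturbed_by_l4": s.unperturbed_by_l4,
                "unperturbed_by_l3": s.unperturbed_by_l3,
                "reciprocal": s.reciprocal,
                "c_only_reciprocal": s.c_only_reciprocal,
                "c_only_reciprocal_down_l3_up_l4": s.c_only_reciprocal_down_l3_up_l4,
                "c_only_reciprocal_up_l3_down_l4": s.c_only_reciprocal_up_l3_down_l4,
                "l4_sig_unique": s.l4_sig_unique,
                "l4_sig_unique_same_direction": s.l4_sig_unique_same_direction,
                "same_direction_weak_l4": s.same_direction_weak_l4,
            }
        out["reciprocal_total"] = self.reciprocal_total
        out["lambda4_unique_total"] = self.lambda4_unique_total
        out["lambda4_unique_same_direction_total"] = self.lambda4_unique_same_direction_total
        return out


def _summarize_one(classes: pd.DataFrame) -> CellTypeSummary:
    region_counts = {r: 0 for r in REGIONS}
    for r, n in classes["venn_region"].value_counts().items():
        region_counts[r] = int(n)
    category_counts = {c: 0 for c in CATEGORIES}
    for c, n in classes["category"].value_counts().items():
        category_counts[c] = int(n)

    # headline counts are over the Venn membership (significant in >= 1
    # contrast): a weak-weak opposite pair that never reaches significance
    # is classified reciprocal gene-wise but appears in no diagram
    in_venn = classes["venn_region"] != "none"
    recip = (classes["category"] == "reciprocal") & in_venn
    c_only = classes["venn_region"] == "C_only"
    sig_unique4 = classes["sig_l4"] & ~classes["sig_l3"]
    same_dir = (classes["dir_l3"] == classes["dir_l4"]) & (classes["dir_l3"] != 0)

    return CellTypeSummary(
        region_counts=region_counts,
        category_counts=category_counts,
        n_significant=int(in_venn.sum()),
        unperturbed_by_l4=int((in_venn & ~classes["perturbed_l4"]).sum()),
        unperturbed_by_l3=int((in_venn & ~classes["perturbed_l3"]).sum()),
        reciprocal=int(recip.sum()),
        c_only_reciprocal=int((recip & c_only).sum()),
        c_only_reciprocal_down_l3_up_l4=int(
            (recip & c_only & (classes["dir_l3"] == -1) & (classes["dir_l4"] == 1)).sum()
        ),
        c_only_reciprocal_up_l3_down_l4=int(
            (recip & c_only & (classes["dir_l3"] == 1) & (classes["dir_l4"] == -1)).sum()
        ),
        l4_sig_unique=int(sig_unique4.sum()),
        l4_sig_unique_same_direction=int((sig_unique4 & same_dir).sum()),
        same_direction_weak_l4=int(
            (
                in_venn
                & (classes["category"] == "same_direction")
                & (classes["tier_l4"] == "weak")
            ).sum()
        ),
    )


def summarize(classes_by_cell_type: Mapping[str, pd.DataFrame]) -> ClassificationSummary:
    """Aggregate per-gene classifications into the study's headline counts.

    Input: mapping cell type -> output of :func:`classify_table`.  Region
    counts over the seven Venn regions sum to the number of genes
    significant in at least one contrast; category counts partition all
    classified genes.
    """
    summary = ClassificationSummary()
    for ct, classes in classes_by_cell_type.items():
        summary.per_cell_type[ct] = _summarize_one(classes)
    return summary
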