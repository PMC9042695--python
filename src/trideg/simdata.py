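"""Synthetic count data and deterministic classification fixtures.

Two generators live here:

* :func:`simulate_counts` draws a negative-binomial gene x sample count
  matrix over the full donor x cell-type x treatment grid, with planted
  gene archetypes (per-gene log2 fold changes for each interferon) so
  that the downstream pipeline's recovery can be measured against known
  truth.
* :func:`build_fixture` emits per-gene three-contrast (fold change,
  p-value) rows *constructed*, not simulated, to land in a requested Venn
  region with requested tiers and directions — a deterministic stand-in
  for the study's classified gene sets that exercises the classification
  algebra without any statistics.

The default simulation emulates the study design: 4 donors, M1 and M2
macrophages, three treatments (NT, IFN-λ3, IFN-λ4), NB counts with a
common dispersion, log-uniform library sizes spanning a 4-fold range (so
TMM normalization is doing real work), and an attenuation of IFN-λ4
effects in M2 cells reflecting the higher signalling threshold IFN-λ4
shows in that polarization state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import REGIONS, TIERS, TierThresholds

__all__ = [
    "ARCHETYPES",
    "SimConfig",
    "RegionBlock",
    "simulate_counts",
    "build_fixture",
    "reference_region_counts",
    "write_counts",
    "read_counts",
    "write_design",
    "read_design",
]

#: Planted per-gene response archetypes.  Tier names refer to the planted
#: |log2FC| drawn from SimConfig.effect_sizes; "opposite"/"same" describe
#: the relative direction of the λ3 and λ4 effects.
ARCHETYPES = (
    "null",
    "l3_only",
    "l4_only",
    "shared_same",
    "reciprocal",
    "weak_l4_moderate_l3_same",
    "weak_l4_strong_l3",
    "weak_weak_opposite",
)


def _default_mix() -> dict[str, float]:
    return {
        "null": 0.70,
        "l3_only": 0.08,
        "l4_only": 0.04,
        "shared_same": 0.06,
        "reciprocal": 0.06,
        "weak_l4_moderate_l3_same": 0.03,
        "weak_l4_strong_l3": 0.02,
        "weak_weak_opposite": 0.01,
    }


def _default_effects() -> dict[str, float]:
    return {"strong": 2.0, "moderate": 1.0, "weak": 0.45}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic count generator.

    baseline_log2_cpm_range: per-gene baseline expression, log2 CPM,
    drawn uniformly.  dispersion: NB dispersion φ with variance μ + φμ².
    library_size_range: per-sample total counts, drawn log-uniformly.
    effect_sizes: |log2FC| planted for each tier.  m2_l4_attenuation:
    multiplier applied to λ4 effects in M2 cells.  cell_type_effect_sd:
    SD of a per-gene log2 offset between M2 and M1 baselines (macrophage
    polarization itself reshapes the transcriptome, which is what lets
    cell types separate in a PCA).
    """

    n_genes: int = 2000
    n_donors: int = 4
    cell_types: tuple[str, ...] = ("M1", "M2")
    treatments: tuple[str, ...] = ("NT", "IFNL3", "IFNL4")
    baseline_log2_cpm_range: tuple[float, float] = (3.0, 10.0)
    dispersion: float = 0.1
    library_size_range: tuple[int, int] = (500_000, 2_000_000)
    archetype_mix: dict[str, float] = field(default_factory=_default_mix)
    effect_sizes: dict[str, float] = field(default_factory=_default_effects)
    m2_l4_attenuation: float = 0.25
    cell_type_effect_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_donors <= 0:
            raise ValueError("n_genes and n_donors must be positive")
        if self.dispersion < 0:
            raise ValueError(f"dispersion must be >= 0, got {self.dispersion}")
        if self.library_size_range[0] <= 0 or self.library_size_range[0] > self.library_size_range[1]:
            raise ValueError(f"malformed library_size_range {self.library_size_range}")
        unknown = set(self.archetype_mix) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes in mix: {sorted(unknown)}")
        if any(v < 0 for v in self.archetype_mix.values()):
            raise ValueError("archetype_mix proportions must be nonnegative")
        total = sum(self.archetype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype_mix proportions must sum to 1, got {total}")
        es = self.effect_sizes
        if not (es["strong"] > es["moderate"] > es["weak"] > 0):
            raise ValueError(f"effect sizes must be ordered strong > moderate > weak > 0, got {es}")


def _planted_lfc(archetype: str, sign: int, es: Mapping[str, float]) -> tuple[float, float]:
    """(log2FC_l3, log2FC_l4) vs NT for one gene, before M2 attenuation."""
    s, m, w = es["strong"], es["moderate"], es["weak"]
    if archetype == "null":
        return 0.0, 0.0
    if archetype == "l3_only":
        return sign * s, 0.0
    if archetype == "l4_only":
        return 0.0, sign * s
    if archetype == "shared_same":
        return sign * m, sign * m
    if archetype == "reciprocal":
        return sign * s, -sign * s
    if archetype == "weak_l4_moderate_l3_same":
        return sign * m, sign * w
    if archetype == "weak_l4_strong_l3":
        return sign * s, sign * w
    if archetype == "weak_weak_opposite":
        return sign * w, -sign * w
    raise ValueError(f"unknown archetype {archetype!r}")


def simulate_counts(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw (counts, design, truth) for the full study grid.

    counts: genes x samples nonnegative integers.  design: one row per
    sample with donor, cell_type, treatment.  truth: one row per gene and
    cell type with the archetype label and the planted log2 fold changes
    actually applied in that cell type (after M2 λ4 attenuation).

    Identical config (including seed) gives bit-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    genes = [f"G{i:05d}" for i in range(n)]

    # per-gene baseline and archetype
    lo, hi = cfg.baseline_log2_cpm_range
    base_log2_cpm = rng.uniform(lo, hi, size=n)
    labels = sorted(cfg.archetype_mix)
    probs = np.array([cfg.archetype_mix[a] for a in labels])
    archetype = rng.choice(len(labels), size=n, p=probs / probs.sum())
    archetype = np.array([labels[i] for i in archetype])
    sign = rng.choice([-1, 1], size=n)
    m2_offset = rng.normal(0.0, cfg.cell_type_effect_sd, size=n)

    lfc3 = np.empty(n)
    lfc4 = np.empty(n)
    for i in range(n):
        lfc3[i], lfc4[i] = _planted_lfc(archetype[i], int(sign[i]), cfg.effect_sizes)

    # design grid
    rows = []
    for ct in cfg.cell_types:
        for tr in cfg.treatments:
            for d in range(1, cfg.n_donors + 1):
                sid = f"{ct}_{tr}_D{d}"
                rows.append({"sample": sid, "donor": f"D{d}", "cell_type": ct, "treatment": tr})
    design = pd.DataFrame(rows).set_index("sample")

    # truth per gene and cell type
    truth_rows = []
    lfc_by_ct: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for ct in cfg.cell_types:
        att = cfg.m2_l4_attenuation if ct == "M2" else 1.0
        l3 = lfc3.copy()
        l4 = lfc4 * att
        lfc_by_ct[ct] = (l3, l4)
        truth_rows.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "cell_type": ct,
                    "archetype": archetype,
                    "planted_lfc_l3": l3,
                    "planted_lfc_l4": l4,
                }
            )
        )
    truth = pd.concat(truth_rows, ignore_index=True)

    # library sizes, log-uniform
    lo_l, hi_l = cfg.library_size_range
    lib = np.exp(rng.uniform(math.log(lo_l), math.log(hi_l), size=len(design)))

    base_cpm = 2.0 ** base_log2_cpm
    counts = np.zeros((n, len(design)), dtype=np.int64)
    for j, (sid, row) in enumerate(design.iterrows()):
        ct, tr = row["cell_type"], row["treatment"]
        l3, l4 = lfc_by_ct[ct]
        cpm = base_cpm.copy()
        if ct == "M2":
            cpm = cpm * 2.0 ** m2_offset
        if tr == "IFNL3":
            cpm = cpm * 2.0 ** l3
        elif tr == "IFNL4":
            cpm = cpm * 2.0 ** l4
        mu = cpm * lib[j] / 1e6
        if cfg.dispersion == 0:
            counts[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / cfg.dispersion
            counts[:, j] = rng.negative_binomial(r, r / (r + mu))

    counts_df = pd.DataFrame(
        counts, index=pd.Index(genes, name="gene"), columns=design.index.rename(None)
    )
    return counts_df, design, truth


# ---------------------------------------------------------------------------
# deterministic fixtures


@dataclass(frozen=True)
class RegionBlock:
    """A block of identical fixture genes.

    Requests ``count`` genes in ``cell_type`` landing in Venn region
    ``region`` with the given effect tiers and directions (+1 / -1 / 0)
    per interferon.  Tiers are explicit because a region + direction pair
    alone does not pin them down (e.g. A_only same-direction rows can
    carry a strong or a moderate λ3 effect, which classify differently).
    """

    cell_type: str
    region: str
    tier_l3: str
    tier_l4: str
    dir_l3: int
    dir_l4: int
    count: int


def _tier_fc(tier: str, direction: int, thr: TierThresholds) -> float:
    """Signed fold change magnitude representative of a tier (its band midpoint)."""
    if tier == "null":
        return 1.0
    mag = {
        "strong": 2.0 * thr.strong_fc,
        "moderate": math.sqrt(thr.fc_thresh * thr.strong_fc),
        "weak": math.sqrt(thr.weak_floor_fc * thr.fc_thresh),
    }[tier]
    return mag if direction > 0 else -mag


def _signed_to_log2(fc: float) -> float:
    return math.log2(fc) if fc > 0 else -math.log2(-fc)


def _log2_to_signed(lfc: float) -> float:
    return 2.0 ** lfc if lfc >= 0 else -(2.0 ** -lfc)


def _validate_block(b: RegionBlock, thr: TierThresholds) -> None:
    if b.region not in REGIONS or b.region == "none":
        raise ValueError(f"unknown or empty Venn region {b.region!r}")
    if b.count < 0:
        raise ValueError(f"negative count in block {b}")
    for tier, direction, name in (
        (b.tier_l3, b.dir_l3, "l3"),
        (b.tier_l4, b.dir_l4, "l4"),
    ):
        if tier not in TIERS:
            raise ValueError(f"unknown tier {tier!r}")
        if (tier == "null") != (direction == 0):
            raise ValueError(
                f"direction must be 0 exactly for null tiers ({name} in {b})"
            )
    in_a = b.region in ("A_only", "AB", "AC", "ABC")
    in_b = b.region in ("B_only", "AB", "BC", "ABC")
    in_c = b.region in ("C_only", "AC", "BC", "ABC")
    if in_a != (b.tier_l3 in ("strong", "moderate")):
        raise ValueError(
            f"region {b.region} requires λ3 significance vs NT iff tier is "
            f"strong/moderate; got tier_l3={b.tier_l3} in {b}"
        )
    if in_b != (b.tier_l4 in ("strong", "moderate")):
        raise ValueError(
            f"region {b.region} requires λ4 significance vs NT iff tier is "
            f"strong/moderate; got tier_l4={b.tier_l4} in {b}"
        )
    if in_c and (b.tier_l3 == "null" or b.tier_l4 == "null"):
        raise ValueError(
            f"a gene significant in the λ4-vs-λ3 contrast cannot carry a null "
            f"tier (it is at least weakly affected); offending block {b}"
        )


#: Fixed fixture p-values: comfortably significant / comfortably not.
_P_SIG = 1e-4
_P_NS = 0.5


def build_fixture(
    blocks: Sequence[RegionBlock],
    thresholds: TierThresholds = TierThresholds(),
) -> pd.DataFrame:
    """Emit a deterministic per-gene three-contrast table from region blocks.

    Each emitted row re-evaluates, under :func:`trideg.classify.classify_gene`
    with the same thresholds, to exactly the requested region, tiers and
    directions.  Fold changes are tier-band midpoints and p-values fixed
    constants: the fixture tests classification algebra, not inference.

    Columns: cell_type plus the six triplet columns (signed FC and p per
    contrast); index is a synthetic gene id unique across blocks.
    """
    rows = []
    counter = 0
    for b in blocks:
        _validate_block(b, thresholds)
        in_c = b.region in ("C_only", "AC", "BC", "ABC")
        fc3 = _tier_fc(b.tier_l3, b.dir_l3, thresholds)
        fc4 = _tier_fc(b.tier_l4, b.dir_l4, thresholds)
        lfc_c = _signed_to_log2(fc4) - _signed_to_log2(fc3) if (fc3 and fc4) else 0.0
        fc_c = _log2_to_signed(lfc_c)
        if in_c and abs(fc_c) <= thresholds.fc_thresh:
            # the two vs-NT effects are too alike to carry the C contrast on
            # their own; force a clear λ4-vs-λ3 change in the implied direction
            s = 1 if lfc_c >= 0 else -1
            fc_c = s * math.sqrt(thresholds.fc_thresh * thresholds.strong_fc)
        for _ in range(b.count):
            rows.append(
                {
                    "gene": f"FX{counter:05d}",
                    "cell_type": b.cell_type,
                    "signed_fc_l3": fc3,
                    "p_l3": _P_SIG if b.tier_l3 in ("strong", "moderate") else _P_NS,
                    "signed_fc_l4": fc4,
                    "p_l4": _P_SIG if b.tier_l4 in ("strong", "moderate") else _P_NS,
                    "signed_fc_l4vl3": fc_c,
                    "p_l4vl3": _P_SIG if in_c else _P_NS,
                }
            )
            counter += 1
    cols = ["cell_type", "signed_fc_l3", "p_l3", "signed_fc_l4", "p_l4",
            "signed_fc_l4vl3", "p_l4vl3"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows).set_index("gene")[cols]


def reference_region_counts() -> list[RegionBlock]:
    """The canonical worked example: the study's printed M1/M2 region counts.

    M1 macrophages: 521 genes unique to the λ4-vs-λ3 contrast, all
    reciprocally driven (290 down by λ3 / up by λ4, 231 the reverse); 9
    reciprocal genes significant in all three contrasts; 433 genes with a
    moderate λ3 and weak same-direction λ4 effect (λ3-significant only);
    126 the mirror image (λ4-significant only); 103 genes strongly driven
    by λ4 with a weak opposite λ3 effect.  M2 macrophages: 1707 genes
    strongly driven by λ3 with λ4 left unperturbed; 587 moderate-λ3 /
    weak-λ4 same-direction genes; 230 reciprocal contrast-only genes (and
    one significant in all three); 10 λ4-significant-only same-direction
    genes and 3 strong-λ4 / weak-opposite-λ3 genes.
    """
    return [
        # --- M1 ---
        RegionBlock("M1", "C_only", "weak", "weak", -1, +1, 290),
        RegionBlock("M1", "C_only", "weak", "weak", +1, -1, 231),
        RegionBlock("M1", "ABC", "moderate", "moderate", +1, -1, 9),
        RegionBlock("M1", "A_only", "moderate", "weak", +1, +1, 433),
        RegionBlock("M1", "B_only", "weak", "moderate", +1, +1, 126),
        RegionBlock("M1", "BC", "weak", "strong", -1, +1, 103),
        # --- M2 ---
        RegionBlock("M2", "C_only", "weak", "weak", -1, +1, 115),
        RegionBlock("M2", "C_only", "weak", "weak", +1, -1, 115),
        RegionBlock("M2", "ABC", "moderate", "moderate", +1, -1, 1),
        RegionBlock("M2", "A_only", "strong", "weak", +1, +1, 1707),
        RegionBlock("M2", "A_only", "moderate", "weak", +1, +1, 587),
        RegionBlock("M2", "B_only", "weak", "moderate", +1, +1, 10),
        RegionBlock("M2", "BC", "weak", "strong", -1, +1, 3),
    ]


# ---------------------------------------------------------------------------
# plain-text IO


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    return df


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index_label="sample")


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "sample"
    required = {"donor", "cell_type", "treatment"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table is missing columns: {sorted(missing)}")
    return df
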