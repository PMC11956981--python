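"""Component enrichment of Delta-Maps against tissue segmentation masks.

For each sub-transition the endpoint masks are merged (per-pixel maximum
label), "ghost nuclei" present in only one endpoint are removed, and nuclei
and vasculature are integrated into a composite component map (3 = tumor
nuclei, 2 = non-tumor nuclei, 1 = vasculature, 0 = other; nucleus/vessel
conflicts resolved by a fair seeded coin).  Per patch, the binarized
Delta-Map's Jaccard index with each component is compared with the index
against a random same-transition patch's composite; the per-component median
ratio and a one-sided paired t-test quantify enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

logger = logging.getLogger(__name__)

__all__ = [
    "CompositeMap",
    "EnrichmentTable",
    "merge_masks",
    "remove_ghost_nuclei",
    "build_composite",
    "jaccard_components",
    "enrichment_analysis",
]

_EIGHT = np.ones((3, 3), dtype=bool)
COMPONENT_NAMES = {3: "tumor_nuclei", 2: "non_tumor_nuclei", 1: "vasculature", 0: "other"}


@dataclass
class CompositeMap:
    labels: np.ndarray  # H x W in {0,1,2,3}
    provenance: tuple = ("", "")
    rng_seed: int = 0


@dataclass
class EnrichmentTable:
    rows: pd.DataFrame  # patch_id, transition, component, j_true, j_rand, ratio
    aggregates: pd.DataFrame  # transition, component, median_ratio, p_value, n


def merge_masks(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Per-pixel maximum label of two aligned masks."""
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}")
    return np.maximum(mask_a, mask_b)


def remove_ghost_nuclei(
    merged_nuclei: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray
) -> np.ndarray:
    """Drop merged nucleus components absent from either source mask.

    A nucleus component of the merged mask is kept only if it overlaps at
    least one nucleus pixel in both sources; removed components are set to 0.
    """
    lab, n = ndimage.label(merged_nuclei > 0, structure=_EIGHT)
    if n == 0:
        return merged_nuclei.copy()
    in_a = ndimage.maximum(mask_a > 0, lab, index=range(1, n + 1))
    in_b = ndimage.maximum(mask_b > 0, lab, index=range(1, n + 1))
    keep = np.concatenate([[False], np.asarray(in_a, bool) & np.asarray(in_b, bool)])
    out = merged_nuclei.copy()
    out[~keep[lab]] = 0
    return out


def build_composite(
    nuclei_merged_clean: np.ndarray,
    vasc_merged: np.ndarray,
    seed: int = 0,
    provenance: tuple = ("", ""),
) -> CompositeMap:
    """Integrate nuclei and vessel masks into component codes {0,1,2,3}.

    Nucleus codes map 2 -> 3 (tumor) and 1 -> 2 (non-tumor); vessel-only
    pixels get 1.  Pixels claimed by both a nucleus and the vessel mask are
    reassigned by a fair seeded coin to either side, deterministically given
    the seed.
    """
    if nuclei_merged_clean.shape != vasc_merged.shape:
        raise ValueError("mask shapes differ")
    comp = np.zeros(nuclei_merged_clean.shape, dtype=np.uint8)
    comp[nuclei_merged_clean == 1] = 2
    comp[nuclei_merged_clean == 2] = 3
    vessel = vasc_merged > 0
    comp[vessel & (nuclei_merged_clean == 0)] = 1
    conflict = vessel & (nuclei_merged_clean > 0)
    n_conf = int(conflict.sum())
    if n_conf:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC01]))
        to_vessel = rng.random(n_conf) < 0.5
        cy, cx = np.nonzero(conflict)
        comp[cy[to_vessel], cx[to_vessel]] = 1
    return CompositeMap(labels=comp, provenance=provenance, rng_seed=int(seed))


def composite_from_patches(patch_a, patch_b, seed: int = 0) -> CompositeMap:
    """Merged/ghost-cleaned/conflict-resolved composite of two endpoint patches."""
    nuc = merge_masks(patch_a.nuclei_mask, patch_b.nuclei_mask)
    nuc = remove_ghost_nuclei(nuc, patch_a.nuclei_mask, patch_b.nuclei_mask)
    vasc = merge_masks(patch_a.vasc_mask, patch_b.vasc_mask)
    return build_composite(
        nuc, vasc, seed=seed, provenance=(patch_a.patch_id, patch_b.patch_id)
    )


def jaccard_components(binary_delta: np.ndarray, composite: CompositeMap) -> dict:
    """Jaccard index of the binary Delta-Map with each component's mask.

    Components whose union with the map is empty get NaN (undefined).
    """
    b = np.asarray(binary_delta, bool)
    if b.shape != composite.labels.shape:
        raise ValueError("binary map and composite shapes differ")
    out = {}
    for code in (0, 1, 2, 3):
        m = composite.labels == code
        union = int((b | m).sum())
        out[code] = float((b & m).sum()) / union if union else float("nan")
    return out


@dataclass
class EnrichmentItem:
    """One patch's contribution: its binary Delta-Map and its own composite."""

    patch_id: str
    transition: str
    binary_delta: np.ndarray
    composite: CompositeMap


def enrichment_analysis(
    items: list,
    seed: int = 0,
    baseline_draws: int = 1,
    paired: bool = True,
) -> EnrichmentTable:
    """True-vs-random Jaccard enrichment over a cohort of marched patches.

    Per patch: Jaccard against its own composite and against the composite of
    a uniformly drawn different patch of the same transition (averaged over
    ``baseline_draws`` draws).  Aggregates per (transition, component): median
    ratio and one-sided t-test p-value of J_true > J_rand (paired by default).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xE17]))
    rows = []
    by_transition: dict[str, list[int]] = {}
    for i, it in enumerate(items):
        by_transition.setdefault(it.transition, []).append(i)

    for trans, idxs in by_transition.items():
        for i in idxs:
            it = items[i]
            j_true = jaccard_components(it.binary_delta, it.composite)
            others = [j for j in idxs if j != i]
            if not others:
                for code in (0, 1, 2, 3):
                    rows.append(
                        dict(patch_id=it.patch_id, transition=trans,
                             component=COMPONENT_NAMES[code], j_true=j_true[code],
                             j_rand=np.nan, ratio=np.nan)
                    )
                logger.warning("transition %s has a single patch; no baseline", trans)
                continue
            j_rand_acc = {c: [] for c in (0, 1, 2, 3)}
            for _ in range(baseline_draws):
                other = items[others[int(rng.integers(len(others)))]]
                jr = jaccard_components(it.binary_delta, other.composite)
                for c in (0, 1, 2, 3):
                    j_rand_acc[c].append(jr[c])
            for code in (0, 1, 2, 3):
                jt = j_true[code]
                jr = float(np.nanmean(j_rand_acc[code])) if j_rand_acc[code] else np.nan
                if np.isnan(jt) or np.isnan(jr):
                    ratio = np.nan
                elif jr == 0:
                    ratio = np.inf if jt > 0 else np.nan
                else:
                    ratio = jt / jr
                rows.append(
                    dict(patch_id=it.patch_id, transition=trans,
                         component=COMPONENT_NAMES[code], j_true=jt, j_rand=jr, ratio=ratio)
                )

    df = pd.DataFrame(rows)
    aggs = []
    for (trans, comp), grp in df.groupby(["transition", "component"], sort=True):
        ratios = grp["ratio"].to_numpy()
        finite_or_inf = ratios[~np.isnan(ratios)]
        n_inf = int(np.isinf(finite_or_inf).sum())
        if finite_or_inf.size and n_inf / max(finite_or_inf.size, 1) > 0.05:
            logger.warning(
                "%s/%s: %d/%d infinite ratios (zero baselines)",
                trans, comp, n_inf, finite_or_inf.size,
            )
        median_ratio = float(np.median(finite_or_inf)) if finite_or_inf.size else np.nan
        ok = grp.dropna(subset=["j_true", "j_rand"])
        if len(ok) >= 3 and ok["j_true"].std() + ok["j_rand"].std() > 0:
            if paired:
                res = stats.ttest_rel(ok["j_true"], ok["j_rand"], alternative="greater")
            else:
                res = stats.ttest_ind(ok["j_true"], ok["j_rand"], alternative="greater")
            pval = float(res.pvalue)
        else:
            pval = np.nan
        aggs.append(
            dict(transition=trans, component=comp, median_ratio=median_ratio,
                 p_value=pval, n=int(len(grp)))
        )
    return EnrichmentTable(rows=df, aggregates=pd.DataFrame(aggs))
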