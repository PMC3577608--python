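"""Discriminative edge maps and state / trait / compensatory signatures.

Each LOOCV fold yields one weight vector per one-against-rest classifier
in that fold's PCA subspace. Because every fold has its own basis, each
fold's weights are first mapped back to edge space through that fold's
own transform and then averaged across folds; edges are ranked by the
absolute magnitude of the averaged weight.

Signature mapping (configurable): the patient-vs-rest classifier yields
the state set (what sets patients apart from everyone), control-vs-rest
yields the trait set (what the two genetically loaded groups share
against controls), and sibling-vs-rest yields the compensatory set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .connectivity import edge_to_pair, n_edges
from .model import CVResult, PCATransform
from .synthetic import CLASS_ORDER, GroundTruth

__all__ = [
    "EdgeWeightMap",
    "SignatureSet",
    "backproject",
    "average_fold_weights",
    "edge_weight_maps",
    "top_fraction",
    "derive_signatures",
    "label_edges",
    "enrichment_pvalue",
    "evaluate_recovery",
]

DEFAULT_FRACTION = 0.05

#: classifier (class-vs-rest) -> signature name
CLASSIFIER_TO_SIGNATURE: dict[str, str] = {
    "patient": "state",
    "control": "trait",
    "sibling": "compensatory",
}


def backproject(pca: PCATransform, w: np.ndarray) -> np.ndarray:
    """Map a subspace weight vector back to the original edge space.

    Returns ``loadings @ w``. Because the loading columns are
    orthonormal, the back-projected vector satisfies
    ``(loadings @ w) . (x - mean) == w . transform(x)`` for every x, so
    decision values are unchanged.
    """
    w = np.asarray(w, dtype=float)
    if w.shape[0] != pca.d:
        raise ValueError(f"weight length {w.shape[0]} != {pca.d} components")
    return pca.loadings @ w


def average_fold_weights(
    per_fold_weights: Sequence[np.ndarray],
    per_fold_pca: Sequence[PCATransform],
) -> np.ndarray:
    """Back-project each fold's weights with its own transform, then average."""
    if not per_fold_weights:
        raise ValueError("no folds")
    if len(per_fold_weights) != len(per_fold_pca):
        raise ValueError("fold weight and transform counts differ")
    acc = np.zeros(per_fold_pca[0].p)
    for w, pca in zip(per_fold_weights, per_fold_pca):
        acc += backproject(pca, w)
    return acc / len(per_fold_weights)


@dataclass
class EdgeWeightMap:
    """Fold-averaged edge-space weights of one one-against-rest classifier."""

    classifier_id: str
    weights: np.ndarray
    n_regions: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.size != n_edges(self.n_regions):
            raise ValueError("weight length does not match edge count")

    @property
    def rank(self) -> np.ndarray:
        """Edge indices by descending |weight|; ties go to the lower index."""
        return np.lexsort((np.arange(self.weights.size), -np.abs(self.weights)))


def edge_weight_maps(cv: CVResult, n_regions: int) -> dict[str, EdgeWeightMap]:
    """One fold-averaged edge map per one-against-rest classifier."""
    maps = {}
    for k, cls in enumerate(cv.class_order):
        weights = average_fold_weights(
            [fold_w[k] for fold_w in cv.fold_weights], cv.fold_pcas
        )
        maps[cls] = EdgeWeightMap(
            classifier_id=cls, weights=weights, n_regions=n_regions
        )
    return maps


def top_fraction(
    weight_map: EdgeWeightMap,
    fraction: float = DEFAULT_FRACTION,
    top_k: int | None = None,
) -> np.ndarray:
    """The floor(fraction * E) edges of largest |weight|, in rank order.

    ``top_k`` overrides the fraction with an explicit count (e.g. 330
    instead of the computed floor(0.05 * 6670) = 333).
    """
    if top_k is None:
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        top_k = int(np.floor(fraction * weight_map.weights.size))
    if not 0 <= top_k <= weight_map.weights.size:
        raise ValueError("top_k out of range")
    return weight_map.rank[:top_k]


@dataclass
class SignatureSet:
    """Ranked top edges per classifier and the derived signature sets."""

    state_edges: np.ndarray
    trait_edges: np.ndarray
    compensatory_edges: np.ndarray
    per_classifier_top: dict[str, np.ndarray]
    selection_fraction: float
    top_k: int
    n_regions: int

    def edges_for(self, signature: str) -> np.ndarray:
        return {
            "state": self.state_edges,
            "trait": self.trait_edges,
            "compensatory": self.compensatory_edges,
        }[signature]

    def overlaps(self) -> dict[str, int]:
        s = {k: set(v.tolist()) for k, v in self.per_classifier_top.items()}
        keys = sorted(s)
        return {
            f"{a}&{b}": len(s[a] & s[b])
            for ai, a in enumerate(keys)
            for b in keys[ai + 1 :]
        }


def derive_signatures(
    maps: Mapping[str, EdgeWeightMap],
    fraction: float = DEFAULT_FRACTION,
    top_k: int | None = None,
    mapping: Mapping[str, str] = CLASSIFIER_TO_SIGNATURE,
) -> SignatureSet:
    """Select each classifier's top edges and name them per the mapping."""
    missing = set(mapping) - set(maps)
    if missing:
        raise ValueError(f"missing classifier maps: {sorted(missing)}")
    tops = {cls: top_fraction(maps[cls], fraction, top_k) for cls in mapping}
    by_signature = {mapping[cls]: tops[cls] for cls in mapping}
    any_top = next(iter(tops.values()))
    return SignatureSet(
        state_edges=by_signature["state"],
        trait_edges=by_signature["trait"],
        compensatory_edges=by_signature["compensatory"],
        per_classifier_top=tops,
        selection_fraction=fraction,
        top_k=len(any_top),
        n_regions=next(iter(maps.values())).n_regions,
    )


def label_edges(
    edges: Iterable[int],
    region_labels: Sequence[str],
    weight_map: EdgeWeightMap,
) -> pd.DataFrame:
    """Report table for an edge set: region names, weight, |weight| rank.

    Region indices in the table are 1-based to match neuroimaging
    reporting conventions; rows are sorted by ascending rank.
    """
    r = weight_map.n_regions
    if len(region_labels) < r:
        raise ValueError("region labels do not cover the parcellation")
    rank_of = np.empty(weight_map.weights.size, dtype=int)
    rank_of[weight_map.rank] = np.arange(1, weight_map.weights.size + 1)
    rows = []
    for e in edges:
        e = int(e)
        i, j = edge_to_pair(e, r)
        rows.append(
            {
                "edge_index": e,
                "region_i": i + 1,
                "region_j": j + 1,
                "region_i_name": region_labels[i],
                "region_j_name": region_labels[j],
                "weight": weight_map.weights[e],
                "rank": int(rank_of[e]),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "edge_index",
            "region_i",
            "region_j",
            "region_i_name",
            "region_j_name",
            "weight",
            "rank",
        ],
    )
    return df.sort_values("rank", ignore_index=True) if len(df) else df


def enrichment_pvalue(
    selected: Iterable[int], planted: Iterable[int], total_edges: int
) -> float:
    """Hypergeometric tail probability of the selected/planted overlap."""
    selected, planted = set(selected), set(planted)
    overlap = len(selected & planted)
    return float(
        hypergeom.sf(overlap - 1, total_edges, len(planted), len(selected))
    )


def evaluate_recovery(
    signatures: SignatureSet, truth: GroundTruth
) -> dict[str, dict[str, float]]:
    """Enrichment of each planted edge set in its matching signature."""
    e = n_edges(signatures.n_regions)
    out = {}
    for name in ("state", "trait", "compensatory"):
        planted = truth.edges_for(name)
        selected = signatures.edges_for(name)
        out[name] = {
            "n_planted": len(planted),
            "n_selected": len(selected),
            "n_recovered": len(set(selected.tolist()) & planted),
            "p_value": enrichment_pvalue(selected, planted, e),
        }
    return out
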