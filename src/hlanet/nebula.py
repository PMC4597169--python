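"""Nebula: two-sided neighbour-edge collaborative filtering for edge labels.

For a queried (HLA h_i, peptide p_x) pair the predictor forms two one-sided
estimates and averages them:

    P(h_i, p_x) = wbar_i + sum_j (w_{j,x} - wbar_j) * S_ij / sum_j S_ij

where j runs over the HLAs connected to p_x (other than h_i), wbar is a
node's mean edge weight over ALL of its incident edges, and S_ij is the
Pearson correlation of h_i's and h_j's weights over the peptides they share,
centred on those same node-level means; S is 0 when the pair shares no
neighbour or either profile has zero spread over the shared set.  The
peptide-side estimate mirrors this with the roles swapped.  The final score
F is the mean of the two sides and the categorical call is positive iff
F >= UL, the unbiased leverage (1.5, midway between the negative weight 1 and
the positive weight 2).

The queried pair's own edge, if present in the network, is never used: it is
removed from every mean, similarity and neighbour sum.  This makes
leave-one-out validation a plain loop over edges with no graph copying.

Degenerate cases are resolved by an explicit fallback cascade, recorded on
the result: a side whose denominator sum of similarities vanishes falls back
to the node mean; a side whose node has no remaining edges is undefined; if
both sides are undefined the global training mean weight is used (when
enabled).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from hlanet.network import BipartiteNetwork, UndefinedMeanError

POSITIVE = "positive"
NEGATIVE = "negative"

SIDE_OK = "ok"
SIDE_ZERO_DENOMINATOR = "zero_denominator"
SIDE_UNDEFINED = "undefined"


@dataclass
class NebulaConfig:
    """Tunable parameters of the Nebula predictor.

    unbiased_leverage
        Decision threshold on F; must lie strictly between the negative (1)
        and positive (2) edge weights.  F >= UL is called positive
        (inclusive boundary).
    denominator_mode
        "literal" divides the deviation sum by sum_j S_ij; "absolute" divides
        by sum_j |S_ij| (the classical collaborative-filtering convention,
        immune to cancellation).
    zero_denominator_epsilon
        |denominator| below this drops the deviation term (node-mean
        fallback for that side).
    global_fallback
        When both sides are undefined, predict the global training mean
        weight instead of refusing.
    """

    unbiased_leverage: float = 1.5
    denominator_mode: str = "literal"
    zero_denominator_epsilon: float = 1e-12
    global_fallback: bool = True

    def __post_init__(self) -> None:
        if not 1.0 < self.unbiased_leverage < 2.0:
            raise ValueError("unbiased_leverage must lie strictly between 1 and 2")
        if self.denominator_mode not in ("literal", "absolute"):
            raise ValueError("denominator_mode must be 'literal' or 'absolute'")


DEFAULT_CONFIG = NebulaConfig()


@dataclass
class PredictionResult:
    """Continuous score F and categorical call C for one queried pair."""

    hla: str
    peptide: str
    F: float
    C: str
    side_hla: Optional[float] = None
    side_peptide: Optional[float] = None
    side_hla_flag: str = SIDE_OK
    side_peptide_flag: str = SIDE_OK
    fallback_used: str = "none"  # none | hla_side_only | peptide_side_only | global_mean

    @property
    def is_positive(self) -> bool:
        return self.C == POSITIVE


def _masked_row(network: BipartiteNetwork, i: int, exclude_j: int | None) -> np.ndarray:
    row = network.W[i]
    if exclude_j is not None and row[exclude_j] != 0:
        row = row.copy()
        row[exclude_j] = 0.0
    return row


def _pearson_over_shared(
    vec_a: np.ndarray, mean_a: float, vec_b: np.ndarray, mean_b: float
) -> float:
    """Pearson correlation of two weight profiles over their shared support,
    centred on the nodes' overall mean weights; 0 on empty or flat support."""
    shared = (vec_a != 0) & (vec_b != 0)
    if not shared.any():
        return 0.0
    da = vec_a[shared] - mean_a
    db = vec_b[shared] - mean_b
    den = np.sqrt((da * da).sum() * (db * db).sum())
    if den == 0.0:
        return 0.0
    return float(np.clip((da * db).sum() / den, -1.0, 1.0))


def similarity_hla(
    network: BipartiteNetwork,
    h_i: str,
    h_j: str,
    exclude: tuple[str, str] | None = None,
) -> float:
    """Pearson similarity of two alleles over their shared peptides.

    ``exclude`` removes one (hla, peptide) edge from the computation (means
    and shared set) when it touches either allele.
    """
    i = network.hla_index(h_i)
    j = network.hla_index(h_j)
    ex_i = network.peptide_index(exclude[1]) if exclude and exclude[0] == h_i else None
    ex_j = network.peptide_index(exclude[1]) if exclude and exclude[0] == h_j else None
    vi = _masked_row(network, i, ex_i)
    vj = _masked_row(network, j, ex_j)
    if not vi.any() or not vj.any():
        raise UndefinedMeanError("allele has no incident edges after exclusion")
    mi = vi[vi != 0].mean()
    mj = vj[vj != 0].mean()
    return _pearson_over_shared(vi, mi, vj, mj)


def similarity_peptide(
    network: BipartiteNetwork,
    p_x: str,
    p_k: str,
    exclude: tuple[str, str] | None = None,
) -> float:
    """Pearson similarity of two peptides over their shared alleles."""
    x = network.peptide_index(p_x)
    k = network.peptide_index(p_k)
    ex_x = network.hla_index(exclude[0]) if exclude and exclude[1] == p_x else None
    ex_k = network.hla_index(exclude[0]) if exclude and exclude[1] == p_k else None
    vx = network.W[:, x]
    vk = network.W[:, k]
    if ex_x is not None and vx[ex_x] != 0:
        vx = vx.copy()
        vx[ex_x] = 0.0
    if ex_k is not None and vk[ex_k] != 0:
        vk = vk.copy()
        vk[ex_k] = 0.0
    if not vx.any() or not vk.any():
        raise UndefinedMeanError("peptide has no incident edges after exclusion")
    mx = vx[vx != 0].mean()
    mk = vk[vk != 0].mean()
    return _pearson_over_shared(vx, mx, vk, mk)


def _predict_side(
    target_vec: np.ndarray,
    neighbor_mat: np.ndarray,
    neighbor_query_weights: np.ndarray,
    config: NebulaConfig,
) -> tuple[Optional[float], str]:
    """One-sided neighbour-edge estimate shared by the HLA and peptide sides.

    ``target_vec`` is the target node's weight profile with the queried edge
    already removed; ``neighbor_mat`` holds the profiles of the opposite-end
    neighbours (the queried edge removed where it appears); and
    ``neighbor_query_weights`` their weights on the queried node.
    """
    support = target_vec != 0
    if not support.any():
        return None, SIDE_UNDEFINED
    mean_t = target_vec[support].mean()
    if neighbor_mat.shape[0] == 0:
        return float(mean_t), SIDE_ZERO_DENOMINATOR
    nb_support = neighbor_mat != 0
    nb_means = neighbor_mat.sum(axis=1) / nb_support.sum(axis=1)
    shared = nb_support & support[None, :]
    dt = target_vec - mean_t
    dn = neighbor_mat - nb_means[:, None]
    num = (dt[None, :] * dn * shared).sum(axis=1)
    sa = ((dt * dt)[None, :] * shared).sum(axis=1)
    sb = (dn * dn * shared).sum(axis=1)
    den = np.sqrt(sa * sb)
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(den > 0, num / den, 0.0)
    S = np.clip(S, -1.0, 1.0)
    denom = np.abs(S).sum() if config.denominator_mode == "absolute" else S.sum()
    if abs(denom) < config.zero_denominator_epsilon:
        return float(mean_t), SIDE_ZERO_DENOMINATOR
    dev = ((neighbor_query_weights - nb_means) * S).sum() / denom
    return float(mean_t + dev), SIDE_OK


def predict_side_hla(
    network: BipartiteNetwork,
    h_i: str,
    p_x: str,
    config: NebulaConfig = DEFAULT_CONFIG,
) -> tuple[Optional[float], str]:
    """HLA-side estimate P(h_i, p_x); the queried pair's own edge is never used.

    Returns (value, flag); value is None with flag "undefined" when h_i has
    no other edges to anchor its mean.
    """
    i = network.hla_index(h_i)
    x = network.peptide_index(p_x)
    target = _masked_row(network, i, x)
    col = network.W[:, x]
    nb_idx = np.nonzero(col)[0]
    nb_idx = nb_idx[nb_idx != i]
    neighbor_mat = network.W[nb_idx]  # rows of other HLAs; their (j, x) edges stay
    return _predict_side(target, neighbor_mat, col[nb_idx], config)


def predict_side_peptide(
    network: BipartiteNetwork,
    p_x: str,
    h_i: str,
    config: NebulaConfig = DEFAULT_CONFIG,
) -> tuple[Optional[float], str]:
    """Peptide-side estimate P(p_x, h_i), mirroring :func:`predict_side_hla`."""
    i = network.hla_index(h_i)
    x = network.peptide_index(p_x)
    target = network.W[:, x]
    if target[i] != 0:
        target = target.copy()
        target[i] = 0.0
    row = network.W[i]
    nb_idx = np.nonzero(row)[0]
    nb_idx = nb_idx[nb_idx != x]
    neighbor_mat = network.W[:, nb_idx].T  # columns of other peptides
    return _predict_side(target, neighbor_mat, row[nb_idx], config)


def predict(
    network: BipartiteNetwork,
    h_i: str,
    p_x: str,
    config: NebulaConfig = DEFAULT_CONFIG,
) -> PredictionResult:
    """Predict the binding label of one (HLA, peptide) pair.

    F averages the defined side estimates (both, or the single defined one);
    when neither side is defined the global training mean weight is used if
    ``config.global_fallback`` allows, otherwise an error is raised.  The
    call is positive iff F >= the unbiased leverage (boundary inclusive).
    """
    vh, fh = predict_side_hla(network, h_i, p_x, config)
    vp, fp = predict_side_peptide(network, p_x, h_i, config)
    if vh is not None and vp is not None:
        F = 0.5 * (vh + vp)
        fallback = "none"
    elif vh is not None:
        F = vh
        fallback = "hla_side_only"
    elif vp is not None:
        F = vp
        fallback = "peptide_side_only"
    else:
        if not config.global_fallback:
            raise UndefinedMeanError(
                f"neither side of ({h_i}, {p_x}) is computable and global fallback is disabled"
            )
        # the queried pair's own edge is excluded from the global mean too
        i = network.hla_index(h_i)
        x = network.peptide_index(p_x)
        mask = network.W != 0
        mask[i, x] = False
        if not mask.any():
            raise UndefinedMeanError("no training edges remain for the global mean")
        F = float(network.W[mask].mean())
        fallback = "global_mean"
    C = POSITIVE if F >= config.unbiased_leverage else NEGATIVE
    return PredictionResult(
        hla=h_i,
        peptide=p_x,
        F=F,
        C=C,
        side_hla=vh,
        side_peptide=vp,
        side_hla_flag=fh,
        side_peptide_flag=fp,
        fallback_used=fallback,
    )


def predict_pairs(
    network: BipartiteNetwork,
    pairs: list[tuple[str, str]],
    config: NebulaConfig = DEFAULT_CONFIG,
) -> list[PredictionResult]:
    """Predict a batch of query pairs against one training network."""
    return [predict(network, h, p, config) for h, p in pairs]


def write_predictions_tsv(results: list[PredictionResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("hla\tpeptide\tF\tC\tfallback\n")
        for r in results:
            fh.write(f"{r.hla}\t{r.peptide}\t{r.F:.6f}\t{r.C}\t{r.fallback_used}\n")
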