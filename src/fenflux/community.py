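"""Community response statistics: who is stimulated by supplemental H2?

Implements a refined LEfSe-style screen for 16S phylotypes responding to H2
addition, plus the supporting nonparametric machinery:

* tie-corrected Kruskal-Wallis test (chi-square p, optional exact
  two-group permutation mode),
* a bootstrap linear-discriminant effect size (:class:`LefseEffectSize`,
  an sklearn-compatible estimator),
* relative-abundance ratios between supplemented and unsupplemented
  treatments,
* the three-criterion stimulation call — a phylotype counts as "stimulated"
  when, for at least one marker type (16S rRNA or 16S rRNA gene), it is
  (a) significantly more abundant (Kruskal-Wallis p <= 0.05), (b) has an
  LDA effect size >= 3, and (c) is on average at least twice as abundant
  in the H2-supplemented treatment,
* a root-treatment abundance screen (>= 1% rRNA or >= 0.5% gene relative
  abundance in any replicate),
* one-sided exact Wilcoxon rank-sum comparisons, Bray-Curtis distances and
  exact-sequence phylotype matching across experiments.

Criterion (c) is the manual refinement: the discriminant score alone admits
features that are only slightly, if very consistently, more abundant.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

MARKERS = ("rRNA", "rRNA_gene")

DEFAULT_P_MAX = 0.05
DEFAULT_LDA_MIN = 3.0
DEFAULT_RATIO_MIN = 2.0


class CommunityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class PhylotypeTable:
    """Feature x sample count (or relative-abundance) table with metadata.

    ``counts`` is features x samples; ``sample_meta`` is indexed by sample id
    with columns ``marker`` (rRNA / rRNA_gene), ``treatment`` and
    ``replicate``; ``feature_meta`` optionally carries representative
    sequences, taxon labels and an ``organelle`` flag.  Organelle-flagged
    features (chloroplast/mitochondria) are dropped at construction.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise CommunityError("duplicate feature ids")
        if self.counts.columns.duplicated().any():
            raise CommunityError("duplicate sample ids")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise CommunityError(f"samples without metadata: {sorted(missing)[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise CommunityError("negative counts")
        bad_marker = set(self.sample_meta["marker"]) - set(MARKERS)
        if bad_marker:
            raise CommunityError(f"unknown marker types {sorted(bad_marker)}")
        if self.feature_meta is not None and "organelle" in self.feature_meta:
            organelle = self.feature_meta.index[
                self.feature_meta["organelle"].fillna(False).astype(bool)
            ]
            self.counts = self.counts.drop(index=organelle, errors="ignore")
            self.feature_meta = self.feature_meta.drop(index=organelle)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample fractions (columns sum to 1)."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            empty = list(totals.index[totals == 0])
            raise CommunityError(f"samples with zero total counts: {empty[:5]}")
        return self.counts / totals

    def samples_for(self, marker: str, treatments: list[str]) -> list[str]:
        meta = self.sample_meta
        mask = (meta["marker"] == marker) & meta["treatment"].isin(treatments)
        return [s for s in self.counts.columns if s in meta.index[mask]]


@dataclass(frozen=True)
class MarkerEvidence:
    """Per-marker inputs to the stimulation decision; ``None`` = unavailable."""

    kw_p: float | None = None
    lda_score: float | None = None
    ra_ratio: float | None = None


@dataclass(frozen=True)
class StimulationRecord:
    phylotype_id: str
    evidence: dict[str, MarkerEvidence]
    passes: dict[str, bool]
    stimulated: bool
    thresholds: tuple[float, float, float] = (
        DEFAULT_P_MAX, DEFAULT_LDA_MIN, DEFAULT_RATIO_MIN
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def _kw_h(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H statistic."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    if tie == 0:
        return 0.0
    return h / tie


def kruskal_wallis(
    groups: list[np.ndarray | list[float]], exact: bool = False
) -> tuple[float, float]:
    """Kruskal-Wallis H and p for >= 2 groups.

    The default p uses the chi-square approximation with k-1 degrees of
    freedom — the convention of the published LEfSe implementation, and the
    only convention under which triplicate designs can reach p <= 0.05.
    ``exact=True`` switches to full enumeration of group assignments
    (two groups only).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise CommunityError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise CommunityError("empty group")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h_obs = _kw_h(arrays)
    if not exact:
        p = float(stats.chi2.sf(h_obs, df=len(arrays) - 1))
        return float(h_obs), p
    if len(arrays) != 2:
        raise NotImplementedError("exact permutation mode supports two groups only")
    n1 = arrays[0].size
    idx = range(pooled.size)
    count = 0
    total = 0
    for combo in itertools.combinations(idx, n1):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(combo)] = True
        h = _kw_h([pooled[mask], pooled[~mask]])
        if h >= h_obs - 1e-12:
            count += 1
        total += 1
    return float(h_obs), count / total


# ---------------------------------------------------------------------------
# LEfSe-style bootstrap LDA effect size
# ---------------------------------------------------------------------------

class LefseEffectSize(BaseEstimator):
    """Bootstrap linear-discriminant effect size for a two-class feature table.

    Follows the published LEfSe recipe: per-sample total-sum scaling to a
    fixed count (1e6), a Kruskal-Wallis screen at ``alpha``, then ``n_boot``
    bootstrap rounds each subsampling ``subsample_fraction`` of every class
    and combining the raw class-mean difference with the feature's loading on
    the Fisher discriminant axis; the reported score is
    ``sign * log10(1 + |mean effect|)`` on the scaled axis.  A diagonal ridge
    regularises the (routinely singular at n=3) within-class scatter.

    Parameters
    ----------
    n_boot : bootstrap rounds (default 30).
    subsample_fraction : per-class subsample fraction per round (default 2/3,
        never fewer than 2 samples).
    alpha : Kruskal-Wallis screen level; features failing it get NaN scores.
    scale : per-sample total after normalisation; ``None`` if the input is
        already on the intended scale.
    positive_class : label whose enrichment is reported with positive sign
        (default: last label in sorted order).
    random_state : required seed for the bootstrap subsampling.

    Attributes
    ----------
    kw_pvalue_ : ndarray (n_features,)
    effect_size_ : signed mean bootstrap effect on the scaled axis
    lda_score_ : signed log10(1 + |effect|); NaN where the screen failed
    classes_ : the two class labels
    """

    def __init__(
        self,
        n_boot: int = 30,
        subsample_fraction: float = 2.0 / 3.0,
        alpha: float = DEFAULT_P_MAX,
        scale: float | None = 1e6,
        positive_class: object | None = None,
        random_state: int | None = None,
    ) -> None:
        self.n_boot = n_boot
        self.subsample_fraction = subsample_fraction
        self.alpha = alpha
        self.scale = scale
        self.positive_class = positive_class
        self.random_state = random_state

    def fit(self, X, y) -> "LefseEffectSize":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise CommunityError("X must be 2d (samples x features)")
        classes = np.unique(y)
        if classes.size != 2:
            raise CommunityError(f"need exactly two classes, got {classes.size}")
        if self.random_state is None:
            raise CommunityError("random_state is a required, recorded input")
        pos = self.positive_class if self.positive_class is not None else classes[-1]
        if pos not in classes:
            raise CommunityError(f"positive_class {pos!r} not among labels")
        neg = classes[classes != pos][0]
        idx_pos = np.flatnonzero(y == pos)
        idx_neg = np.flatnonzero(y == neg)
        if min(idx_pos.size, idx_neg.size) < 2:
            raise CommunityError("each class needs at least two samples")

        if self.scale is not None:
            totals = X.sum(axis=1, keepdims=True)
            if (totals == 0).any():
                raise CommunityError("sample with zero total abundance")
            X = X / totals * self.scale

        n_feat = X.shape[1]
        kw_p = np.empty(n_feat)
        for j in range(n_feat):
            _, kw_p[j] = kruskal_wallis([X[idx_pos, j], X[idx_neg, j]])
        keep = np.flatnonzero(kw_p <= self.alpha)

        effect = np.full(n_feat, np.nan)
        score = np.full(n_feat, np.nan)
        if keep.size:
            rng = np.random.default_rng(self.random_state)
            acc = np.zeros(keep.size)
            n_pos = max(2, math.ceil(self.subsample_fraction * idx_pos.size))
            n_neg = max(2, math.ceil(self.subsample_fraction * idx_neg.size))
            for _ in range(self.n_boot):
                sp = rng.choice(idx_pos, size=n_pos, replace=False)
                sn = rng.choice(idx_neg, size=n_neg, replace=False)
                acc += self._boot_effect(X[sp][:, keep], X[sn][:, keep])
            mean_eff = acc / self.n_boot
            sign = np.sign(
                X[idx_pos][:, keep].mean(axis=0) - X[idx_neg][:, keep].mean(axis=0)
            )
            sign[sign == 0] = 1.0
            effect[keep] = sign * mean_eff
            score[keep] = sign * np.log10(1.0 + np.abs(mean_eff))

        self.classes_ = np.array([neg, pos])
        self.positive_class_ = pos
        self.kw_pvalue_ = kw_p
        self.effect_size_ = effect
        self.lda_score_ = score
        return self

    @staticmethod
    def _boot_effect(xp: np.ndarray, xn: np.ndarray) -> np.ndarray:
        """One bootstrap round: mean of raw and discriminant-projected effects."""
        m_pos = xp.mean(axis=0)
        m_neg = xn.mean(axis=0)
        gm = np.abs(m_pos - m_neg)
        centered = np.vstack([xp - m_pos, xn - m_neg])
        sw = centered.T @ centered / max(1, centered.shape[0] - 2)
        ridge = 1e-6 * (np.trace(sw) / sw.shape[0] + 1.0)
        sw = sw + ridge * np.eye(sw.shape[0])
        w = np.linalg.solve(sw, m_pos - m_neg)
        norm = np.linalg.norm(w)
        if norm == 0:
            return gm / 2.0
        w_unit = w / norm
        ld_gap = abs(float(w_unit @ (m_pos - m_neg)))
        coeff = np.abs(w_unit) * ld_gap
        return (gm + coeff) / 2.0


def lda_effect_size(
    table: PhylotypeTable,
    marker: str,
    h2_treatments: list[str],
    unsupp_treatments: list[str],
    n_boot: int = 30,
    subsample_fraction: float = 2.0 / 3.0,
    seed: int | None = None,
    alpha: float = DEFAULT_P_MAX,
) -> pd.DataFrame:
    """Per-feature LDA scores for one marker and one treatment contrast.

    Returns a DataFrame indexed by feature with ``kw_p``, ``effect_size`` and
    ``lda_score`` columns; scores are positive for enrichment in the
    H2-supplemented class.
    """
    samples = table.samples_for(marker, list(h2_treatments) + list(unsupp_treatments))
    if not samples:
        raise CommunityError(f"no samples for marker {marker!r}")
    ra = table.relative_abundance()[samples]
    y = np.array([
        "h2" if table.sample_meta.loc[s, "treatment"] in h2_treatments else "un"
        for s in samples
    ])
    est = LefseEffectSize(
        n_boot=n_boot, subsample_fraction=subsample_fraction, alpha=alpha,
        positive_class="h2", random_state=seed,
    ).fit(ra.T.to_numpy(), y)
    return pd.DataFrame(
        {"kw_p": est.kw_pvalue_, "effect_size": est.effect_size_,
         "lda_score": est.lda_score_},
        index=ra.index,
    )


# ---------------------------------------------------------------------------
# Ratios and the stimulation decision
# ---------------------------------------------------------------------------

def ra_ratios(
    table: PhylotypeTable,
    marker: str,
    h2_treatments: list[str],
    unsupp_treatments: list[str],
) -> pd.Series:
    """Per-feature mean relative abundance in H2 treatments over mean in
    unsupplemented treatments.

    ``inf`` when a feature is absent from the unsupplemented samples but
    present with H2 (a maximal response); NaN when absent from both.
    """
    ra = table.relative_abundance()
    s_h = table.samples_for(marker, list(h2_treatments))
    s_u = table.samples_for(marker, list(unsupp_treatments))
    if not s_h or not s_u:
        raise CommunityError(f"need >= 1 replicate per treatment for {marker!r}")
    mean_h = ra[s_h].mean(axis=1)
    mean_u = ra[s_u].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mean_h / mean_u
    ratio[(mean_u == 0) & (mean_h > 0)] = math.inf
    ratio[(mean_u == 0) & (mean_h == 0)] = math.nan
    return ratio


def ra_ratio(
    table: PhylotypeTable,
    feature: str,
    marker: str,
    h2_treatments: list[str],
    unsupp_treatments: list[str],
) -> float:
    """Single-feature convenience wrapper over :func:`ra_ratios`."""
    return float(ra_ratios(table, marker, h2_treatments, unsupp_treatments)[feature])


def stimulation_call(
    phylotype_id: str,
    evidence: dict[str, MarkerEvidence],
    p_max: float = DEFAULT_P_MAX,
    lda_min: float = DEFAULT_LDA_MIN,
    ratio_min: float = DEFAULT_RATIO_MIN,
) -> StimulationRecord:
    """Apply the three criteria per marker; stimulated = pass on any marker.

    All bounds are inclusive.  Criterion (c) must hold for the *same* marker
    whose p/LDA passed — a high gene-level ratio cannot rescue an rRNA-level
    discriminant hit.
    """
    if not evidence:
        raise CommunityError("need evidence for at least one marker")
    passes: dict[str, bool] = {}
    for marker, ev in evidence.items():
        a = ev.kw_p is not None and ev.kw_p <= p_max
        b = (
            ev.lda_score is not None
            and not math.isnan(ev.lda_score)
            and ev.lda_score >= lda_min
        )
        c = (
            ev.ra_ratio is not None
            and not math.isnan(ev.ra_ratio)
            and ev.ra_ratio >= ratio_min
        )
        passes[marker] = a and b and c
    return StimulationRecord(
        phylotype_id=phylotype_id,
        evidence=dict(evidence),
        passes=passes,
        stimulated=any(passes.values()),
        thresholds=(p_max, lda_min, ratio_min),
    )


def identify_stimulated(
    table: PhylotypeTable,
    h2_treatments: list[str],
    unsupp_treatments: list[str],
    markers: tuple[str, ...] = MARKERS,
    seed: int | None = None,
    n_boot: int = 30,
    p_max: float = DEFAULT_P_MAX,
    lda_min: float = DEFAULT_LDA_MIN,
    ratio_min: float = DEFAULT_RATIO_MIN,
) -> pd.DataFrame:
    """Run the full refined screen over every feature and available marker.

    Returns a DataFrame indexed by feature with per-marker ``kw_p``,
    ``lda_score`` and ``ra_ratio`` columns plus a boolean ``stimulated``.
    """
    per_marker: dict[str, pd.DataFrame] = {}
    for marker in markers:
        samples = table.samples_for(marker, list(h2_treatments) + list(unsupp_treatments))
        if not samples:
            continue
        scores = lda_effect_size(
            table, marker, h2_treatments, unsupp_treatments,
            n_boot=n_boot, seed=seed, alpha=p_max,
        )
        scores["ra_ratio"] = ra_ratios(table, marker, h2_treatments, unsupp_treatments)
        per_marker[marker] = scores
    if not per_marker:
        raise CommunityError("no marker has samples for the requested treatments")

    out: dict[str, dict] = {}
    for feature in table.counts.index:
        evidence = {}
        row: dict[str, object] = {}
        for marker, scores in per_marker.items():
            s = scores.loc[feature]
            evidence[marker] = MarkerEvidence(
                kw_p=float(s["kw_p"]),
                lda_score=None if math.isnan(s["lda_score"]) else float(s["lda_score"]),
                ra_ratio=float(s["ra_ratio"]),
            )
            row[f"kw_p_{marker}"] = s["kw_p"]
            row[f"lda_score_{marker}"] = s["lda_score"]
            row[f"ra_ratio_{marker}"] = s["ra_ratio"]
        rec = stimulation_call(feature, evidence, p_max, lda_min, ratio_min)
        row["stimulated"] = rec.stimulated
        out[feature] = row
    return pd.DataFrame.from_dict(out, orient="index")


def root_abundance_screen(
    table: PhylotypeTable,
    root_treatments: list[str],
    rrna_min_pct: float = 1.0,
    gene_min_pct: float = 0.5,
) -> list[str]:
    """Features reaching >= 1% rRNA or >= 0.5% gene relative abundance in any
    single replicate of any root treatment (inclusive bounds)."""
    ra_pct = table.relative_abundance() * 100.0
    keep: list[str] = []
    s_rrna = table.samples_for("rRNA", root_treatments)
    s_gene = table.samples_for("rRNA_gene", root_treatments)
    if not s_rrna and not s_gene:
        raise CommunityError("no root-treatment samples for either marker")
    for feature in ra_pct.index:
        hit_rrna = bool(s_rrna) and (ra_pct.loc[feature, s_rrna] >= rrna_min_pct).any()
        hit_gene = bool(s_gene) and (ra_pct.loc[feature, s_gene] >= gene_min_pct).any()
        if hit_rrna or hit_gene:
            keep.append(feature)
    return keep


# ---------------------------------------------------------------------------
# Rank-sum test, distances, sequence matching
# ---------------------------------------------------------------------------

def wilcoxon_one_sided(
    x_h2: list[float] | np.ndarray,
    x_unsupp: list[float] | np.ndarray,
    exact_max_n: int = 12,
) -> float:
    """One-sided Wilcoxon rank-sum p for "H2 treatment greater".

    Exact enumeration of rank-sum assignments (midranks, ties handled) when
    the combined sample size is <= ``exact_max_n``; tie-corrected normal
    approximation above.  Fully tied data return p = 1.
    """
    x = np.asarray(x_h2, dtype=float)
    y = np.asarray(x_unsupp, dtype=float)
    if x.size == 0 or y.size == 0:
        raise CommunityError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    n = pooled.size
    if n <= exact_max_n:
        ranks = stats.rankdata(pooled)
        w_obs = ranks[: x.size].sum()
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), x.size):
            if ranks[list(combo)].sum() >= w_obs - 1e-12:
                count += 1
            total += 1
        return count / total
    res = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
    return float(res.pvalue)


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis distance matrix of a samples x features abundance table.

    Symmetric with zero diagonal and values in [0, 1]; pairs involving an
    all-zero sample are undefined (NaN) and reported with a warning.
    """
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise CommunityError("abundances must be nonnegative")
    zero_rows = matrix.index[values.sum(axis=1) == 0]
    if len(zero_rows):
        warnings.warn(
            f"all-zero samples yield undefined distances: {list(zero_rows)[:5]}",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(values, metric="braycurtis"))
    zero_mask = values.sum(axis=1) == 0
    d[zero_mask, :] = np.nan
    d[:, zero_mask] = np.nan
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def shared_phylotype_match(
    features_a: dict[str, str], features_b: dict[str, str]
) -> list[tuple[str, str]]:
    """Pairs of phylotypes with exactly identical sequences (case-insensitive).

    Sequences are assumed trimmed to the same primer region; identical length
    is implied by exact equality.
    """
    def norm(d: dict[str, str], label: str) -> dict[str, str]:
        out = {}
        for k, s in d.items():
            if not s:
                raise CommunityError(f"empty sequence for {label} feature {k!r}")
            out[k] = s.strip().upper()
        return out

    a = norm(features_a, "a")
    b = norm(features_b, "b")
    by_seq: dict[str, list[str]] = {}
    for k, s in b.items():
        by_seq.setdefault(s, []).append(k)
    pairs = []
    for k, s in a.items():
        for kb in by_seq.get(s, []):
            pairs.append((k, kb))
    return pairs
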