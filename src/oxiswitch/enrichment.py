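"""Mummichog-style pathway activity prediction from m/z feature lists.

Features are tentatively annotated to library compounds by matching their
m/z against mode-consistent adduct ions within a ppm tolerance.  The
significant list is the top fraction of features by p-value (default top
10%%).  Each pathway is scored with the EASE-adjusted Fisher right tail
(hypergeometric P(X >= k-1)) at the compound level, and the raw score is
calibrated against a resampling null: random feature subsets of the
significant-list size are redrawn, all pathway scores recomputed, the
pooled -log10 null scores fit with a gamma distribution (location 0), and
the adjusted p is the gamma survival function at the observed -log10 p.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from oxiswitch.errors import ValidationError
from oxiswitch.ions import adduct_mz, check_mode
from oxiswitch.peaktable import PipelineConfig


@dataclass
class PathwayLibrary:
    """Pathways as compound-code sets plus a code -> neutral mass map."""

    pathways: list[tuple[str, str, tuple[str, ...]]]  # (id, name, codes)
    masses: dict[str, float]

    def __post_init__(self):
        for pid, _name, codes in self.pathways:
            for code in codes:
                if code not in self.masses:
                    raise ValidationError(f"pathway {pid}: compound {code} has no mass entry")
        for code, mass in self.masses.items():
            if not mass > 0:
                raise ValidationError(f"compound {code}: mass must be positive")

    @property
    def pathway_ids(self) -> list[str]:
        return [pid for pid, _, _ in self.pathways]


def read_pathway_library(path: str | Path) -> PathwayLibrary:
    df = pd.read_csv(path, sep="\t")
    for col in ("pathway_id", "name", "compound_code", "neutral_mass"):
        if col not in df.columns:
            raise ValidationError(f"pathway library {path} is missing column {col!r}")
    masses: dict[str, float] = {}
    order: list[str] = []
    names: dict[str, str] = {}
    codes: dict[str, list[str]] = {}
    for r in df.itertuples(index=False):
        pid = str(r.pathway_id)
        code = str(r.compound_code)
        mass = float(r.neutral_mass)
        if code in masses and abs(masses[code] - mass) > 1e-9:
            raise ValidationError(f"compound {code} has conflicting masses")
        masses[code] = mass
        if pid not in codes:
            order.append(pid)
            names[pid] = str(r.name)
            codes[pid] = []
        if code not in codes[pid]:
            codes[pid].append(code)
    pathways = [(pid, names[pid], tuple(codes[pid])) for pid in order]
    return PathwayLibrary(pathways, masses)


def packaged_pathway_library() -> PathwayLibrary:
    """The four reference pathways with masses derived from published formulas."""
    with resources.as_file(resources.files("oxiswitch.data") / "pathways.tsv") as p:
        return read_pathway_library(p)


def annotate_mz(
    features: list[tuple[float, str]], library: PathwayLibrary, ppm: float = 10.0
) -> dict[int, set[str]]:
    """Tentative m/z -> compound annotation.

    ``features`` is a list of ``(mz, mode)``; a feature matches a compound
    iff ``|mz - ion(M)| / ion(M) * 1e6 <= ppm`` for any adduct ion of the
    feature's mode (no isotopologues).  Returns a map from feature index
    to the set of matching compound codes (features with no match are
    absent).  Many-to-many matches are allowed.
    """
    if not ppm > 0:
        raise ValidationError("ppm tolerance must be positive")
    ion_table: dict[str, list[tuple[str, float]]] = {"positive": [], "negative": []}
    for code, mass in library.masses.items():
        for mode in ("positive", "negative"):
            for _label, mz in adduct_mz(mass, mode, isotopologues=False):
                ion_table[mode].append((code, mz))
    ion_arrays = {
        mode: (
            np.array([c for c, _ in pairs]),
            np.array([m for _, m in pairs]),
        )
        for mode, pairs in ion_table.items()
    }
    out: dict[int, set[str]] = {}
    for idx, (mz, mode) in enumerate(features):
        check_mode(mode)
        codes, ions = ion_arrays[mode]
        if ions.size == 0:
            continue
        match = np.abs(mz - ions) / ions * 1e6 <= ppm
        if match.any():
            out[idx] = set(codes[match])
    return out


def select_top_fraction(pvalues, fraction: float = 0.10) -> np.ndarray:
    """Indices of the ceil(fraction * n) smallest p-values; boundary ties
    are all included."""
    if not (0 < fraction <= 1):
        raise ValidationError("fraction must be in (0, 1]")
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    if n == 0:
        return np.array([], dtype=int)
    m = math.ceil(fraction * n)
    cutoff = np.sort(p)[m - 1]
    return np.flatnonzero(p <= cutoff)


def pathway_ease_p(k: int, K: int, n: int, N: int) -> float:
    """EASE-adjusted Fisher right tail: hypergeometric P(X >= k-1).

    Population ``N`` compounds of which ``K`` are in the pathway; ``n``
    drawn (significant); ``k`` observed overlap.  EASE subtracts one from
    the observed overlap; ``k = 0`` gives p = 1.
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"inconsistent contingency counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 2, N, K, n))


@dataclass
class EnrichmentResult:
    pathway_id: str
    name: str
    hit_codes: tuple[str, ...]
    sig_codes: tuple[str, ...]
    n_hits: int
    n_sig_hits: int
    raw_p: float
    adj_p: float
    degenerate_null: bool = False

    def __post_init__(self):
        if not (0 <= self.n_sig_hits <= self.n_hits):
            raise ValidationError("n_sig_hits must lie in [0, n_hits]")


def _incidence(annotations: dict[int, set[str]], n_features: int, code_index: dict[str, int]) -> np.ndarray:
    M = np.zeros((n_features, len(code_index)), dtype=bool)
    for fi, codes in annotations.items():
        for c in codes:
            M[fi, code_index[c]] = True
    return M


def permutation_gamma_adjust(
    observed_raw_p: dict[str, float],
    annotations: dict[int, set[str]],
    n_features: int,
    library: PathwayLibrary,
    n_sig: int,
    permutations: int = 1000,
    seed: int = 0,
) -> tuple[dict[str, float], bool]:
    """Gamma-calibrated permutation adjustment of the raw pathway scores.

    Draws ``permutations`` uniform random feature subsets of size
    ``n_sig`` from all ``n_features`` features, recomputes every
    pathway's EASE p, pools -log10 of the null p-values, fits a gamma
    distribution (location fixed at 0) by maximum likelihood and returns
    ``adj_p[pathway] = gamma.sf(-log10(raw_p))``.  A degenerate null
    (all values identical) falls back to the empirical tail and is
    flagged.  Deterministic given ``seed``.
    """
    if permutations < 100:
        raise ValidationError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    code_index = {c: i for i, c in enumerate(sorted(library.masses))}
    M = _incidence(annotations, n_features, code_index)
    annotated_codes = M.any(axis=0)
    N = int(annotated_codes.sum())
    path_cols = {
        pid: np.array([code_index[c] for c in codes], dtype=int)
        for pid, _name, codes in library.pathways
    }
    Ks = {pid: int(annotated_codes[cols].sum()) for pid, cols in path_cols.items()}

    n_sig = min(n_sig, n_features)
    pids = list(path_cols)
    K_arr = np.array([Ks[pid] for pid in pids])
    null_scores = np.empty(permutations * len(pids))
    pos = 0
    for _ in range(permutations):
        subset = rng.choice(n_features, size=n_sig, replace=False)
        sig_codes = M[subset].any(axis=0)
        n_tot = int(sig_codes.sum())
        k_arr = np.array([int(sig_codes[cols].sum()) for cols in path_cols.values()])
        # vectorized EASE right tail: P(X >= k-1), k = 0 -> 1
        p_arr = stats.hypergeom.sf(k_arr - 2, N, K_arr, n_tot)
        p_arr[k_arr == 0] = 1.0
        null_scores[pos : pos + len(pids)] = p_arr
        pos += len(pids)
    null_log = -np.log10(np.clip(null_scores, 1e-300, 1.0))

    degenerate = bool(np.allclose(null_log, null_log[0]))
    adj: dict[str, float] = {}
    if degenerate:
        for pid, raw in observed_raw_p.items():
            obs = -math.log10(max(raw, 1e-300))
            adj[pid] = float(np.mean(null_log >= obs - 1e-12))
        return adj, True
    # gamma MLE needs strictly positive support
    fit_data = np.maximum(null_log, 1e-6)
    shape, _loc, scale = stats.gamma.fit(fit_data, floc=0)
    for pid, raw in observed_raw_p.items():
        obs = -math.log10(max(raw, 1e-300))
        adj[pid] = float(stats.gamma.sf(obs, shape, loc=0, scale=scale))
    return adj, False


def enrich(
    correlation_table: pd.DataFrame,
    library: PathwayLibrary,
    config: PipelineConfig | None = None,
) -> list[EnrichmentResult]:
    """Full enrichment from a 4-column (m/z, RT, mode, p) feature list.

    Pipeline: annotate -> select top fraction by p -> per-pathway
    compound-level contingency counts -> EASE p -> permutation/gamma
    adjustment.  Results are sorted by adjusted p (ties by raw p then
    pathway id).
    """
    config = config or PipelineConfig()
    for col in ("mz", "mode", "p"):
        if col not in correlation_table.columns:
            raise ValidationError(f"correlation table is missing column {col!r}")
    df = correlation_table.reset_index(drop=True)
    usable = df["p"].notna().to_numpy()
    if not usable.all():
        warnings.warn(f"dropping {int((~usable).sum())} features with undefined p", stacklevel=2)
        df = df[usable].reset_index(drop=True)
    n_features = len(df)
    feats = list(zip(df["mz"].astype(float), df["mode"].astype(str)))
    annotations = annotate_mz(feats, library, config.annotation_ppm)
    if not annotations:
        warnings.warn("no m/z annotations; enrichment result is empty", stacklevel=2)
        return []

    sig_idx = select_top_fraction(df["p"].to_numpy(), config.sig_top_fraction)
    sig_set = set(int(i) for i in sig_idx)
    annotated_codes: set[str] = set()
    sig_codes: set[str] = set()
    for fi, codes in annotations.items():
        annotated_codes |= codes
        if fi in sig_set:
            sig_codes |= codes
    N = len(annotated_codes)
    n = len(sig_codes)

    raw: dict[str, float] = {}
    rows: dict[str, tuple] = {}
    for pid, name, codes in library.pathways:
        hit = tuple(sorted(set(codes) & annotated_codes))
        sig_hit = tuple(sorted(set(codes) & sig_codes))
        raw[pid] = pathway_ease_p(len(sig_hit), len(hit), n, N)
        rows[pid] = (name, hit, sig_hit)

    adj, degenerate = permutation_gamma_adjust(
        raw,
        annotations,
        n_features,
        library,
        n_sig=len(sig_idx),
        permutations=config.permutations,
        seed=config.rng_seed,
    )
    results = [
        EnrichmentResult(
            pathway_id=pid,
            name=rows[pid][0],
            hit_codes=rows[pid][1],
            sig_codes=rows[pid][2],
            n_hits=len(rows[pid][1]),
            n_sig_hits=len(rows[pid][2]),
            raw_p=raw[pid],
            adj_p=adj[pid],
            degenerate_null=degenerate,
        )
        for pid, _name, _codes in library.pathways
    ]
    results.sort(key=lambda r: (r.adj_p, r.raw_p, r.pathway_id))
    return results


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabular enrichment report (pathway, compound codes hit, counts, p)."""
    return pd.DataFrame(
        {
            "pathway_id": [r.pathway_id for r in results],
            "name": [r.name for r in results],
            "compound_codes_hit": ["; ".join(r.sig_codes) for r in results],
            "n_hits": [r.n_hits for r in results],
            "n_sig_hits": [r.n_sig_hits for r in results],
            "raw_p": [r.raw_p for r in results],
            "adj_p": [r.adj_p for r in results],
        }
    )
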