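"""Likelihood-based paternity assignment with known mothers.

The statistical machinery follows the classic categorical-allocation
approach for parentage with codominant markers (Marshall et al. 1998;
Kalinowski et al. 2007).  For each offspring with a known mother, every
candidate male is scored by a log-likelihood ratio (LOD, natural log)
comparing "candidate is the father" against "the father is a random male
from the population", summed over typed loci.  Genotyping error is modelled
as a mistyping mixture: with probability ``e`` an observed genotype is an
independent draw from the Hardy-Weinberg genotype distribution instead of
the true genotype.  Confidence in the best candidate is measured by Delta —
the LOD gap to the runner-up — whose critical values are calibrated by
simulating offspring under the same error/typing regime and asking which
Delta threshold yields the desired proportion of correct assignments.

All per-locus likelihoods are precomputed as 4x4x4 tables (three genotype
states plus missing) so scoring large offspring sets is a table gather.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, CallMatrix

__all__ = [
    "ParentageConfig",
    "PaternityScorer",
    "estimate_allele_freqs",
    "genotype_likelihood",
    "pair_lod",
    "delta_critical",
    "assign_paternity",
]

_MISS_IDX = 3  # index of the "missing" observed state in likelihood tables


@dataclass
class ParentageConfig:
    """Parameters of the assignment and its simulation-based calibration."""

    error_rate: float = 0.01
    prop_sampled: float = 0.95
    prop_typed: float = 0.50
    min_typed_loci: int = 300
    n_sim: int = 10_000
    n_candidates: int = 89
    confidence_levels: dict[str, float] = field(
        default_factory=lambda: {"strict": 0.95, "relaxed": 0.80}
    )
    test_selfing: bool = True

    def __post_init__(self) -> None:
        for name in ("error_rate", "prop_sampled", "prop_typed"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.min_typed_loci < 1:
            raise ValueError("min_typed_loci must be >= 1")


def estimate_allele_freqs(parents: CallMatrix) -> pd.Series:
    """Alternate-allele frequency per marker by allele counting over the
    candidate parents' non-missing calls.  All-missing markers are excluded
    with a warning."""
    g = parents.genotypes
    called = g != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, g, 0).sum(axis=0)
    freqs = pd.Series(
        np.where(n_called > 0, alt / np.maximum(2 * n_called, 1), np.nan),
        index=parents.markers.index,
        name="alt_freq",
    )
    if (n_called == 0).any():
        dropped = freqs.index[n_called == 0]
        warnings.warn(
            f"{len(dropped)} marker(s) with no parental calls excluded from "
            "allele-frequency table",
            stacklevel=2,
        )
        freqs = freqs.drop(dropped)
    return freqs


# ----------------------------------------------------------------------
# per-locus likelihood machinery
# ----------------------------------------------------------------------


def _hwe_priors(q: np.ndarray) -> np.ndarray:
    """(m, 3) Hardy-Weinberg genotype priors for alt-allele frequency q."""
    p = 1.0 - q
    return np.stack([p * p, 2 * p * q, q * q], axis=-1)


def _transmission_tensor() -> np.ndarray:
    """T[go, gm, gf]: Mendelian probability of offspring dosage go given
    parental dosages; each parent transmits the alt allele w.p. g/2."""
    t = np.zeros((3, 3, 3))
    trans = np.array([0.0, 0.5, 1.0])  # P(transmit alt | genotype)
    for gm in range(3):
        for gf in range(3):
            am, af = trans[gm], trans[gf]
            t[0, gm, gf] = (1 - am) * (1 - af)
            t[1, gm, gf] = am * (1 - af) + (1 - am) * af
            t[2, gm, gf] = am * af
    return t


_T = _transmission_tensor()


def _error_matrix(hwe: np.ndarray, e: float) -> np.ndarray:
    """(m, 4, 3) P(observed state | true genotype): with probability e the
    observation is an independent HWE draw; missing observations have
    probability 1 under every true genotype (they carry no information)."""
    m = hwe.shape[0]
    obs = np.empty((m, 4, 3))
    for true in range(3):
        for o in range(3):
            obs[:, o, true] = e * hwe[:, o] + (1.0 - e) * (o == true)
    obs[:, _MISS_IDX, :] = 1.0
    return obs


class PaternityScorer:
    """Precomputed per-marker LOD tables for fast candidate scoring.

    Parameters
    ----------
    freqs
        Alternate-allele frequency per marker (Series or array).
    error_rate
        Mistyping rate ``e`` of the mixture error model.  Values below
        1e-4 are floored at 1e-4 during scoring so that a single
        Mendelian-impossible locus cannot veto a candidate with -inf;
        pass ``floor_error=False`` to disable (used in exact tests).
    """

    def __init__(self, freqs, error_rate: float = 0.01,
                 floor_error: bool = True):
        q = np.asarray(freqs, dtype=float)
        if q.ndim != 1:
            raise ValueError("freqs must be one-dimensional")
        e = max(error_rate, 1e-4) if floor_error else error_rate
        self.error_rate = e
        self.n_markers = len(q)
        hwe = _hwe_priors(q)  # (m, 3)
        obs = _error_matrix(hwe, e)  # (m, 4, 3) observed x true
        # joint trio numerator: P(obs_o, obs_m, obs_f | f is father)
        # = sum_{gm,gf} HWE(gm) HWE(gf) E[om|gm] E[of|gf]
        #     sum_go T[go|gm,gf] E[oo|go]
        to = np.einsum("gab,mog->moab", _T, obs)  # (m, 4obs_o, 3gm, 3gf)
        num = np.einsum(
            "ma,mb,mxa,myb,moab->moxy", hwe, hwe, obs, obs, to
        )  # (m, obs_o, obs_m, obs_f)
        # denominator: father is a random male ->
        # P(obs_o, obs_m) * P(obs_f), with the father term factoring out
        tpop = np.einsum("gab,mb->gam", _T, hwe)  # sum_gf HWE(gf) T
        po_given_gm = np.einsum("mog,gam->moa", obs, tpop)  # (m, obs_o, gm)
        pom = np.einsum("ma,mxa,moa->mox", hwe, obs, po_given_gm)
        pf = np.einsum("mb,myb->my", hwe, obs)  # (m, obs_f)
        den = pom[:, :, :, None] * pf[:, None, None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            self.lod_table = np.log(num) - np.log(den)
        # missing offspring or genuinely zero-probability cells contribute 0
        self.lod_table[:, _MISS_IDX, :, :] = 0.0
        self.lod_table = np.nan_to_num(
            self.lod_table, nan=-np.inf, posinf=np.inf, neginf=-np.inf
        )
        self._trio = num
        self._pop = pom
        self._marg = np.einsum("ma,mxa->mx", hwe, obs)  # P(single obs state)

    # -- helpers ------------------------------------------------------
    @staticmethod
    def _obs_index(g: np.ndarray) -> np.ndarray:
        """Map call codes (-1 missing) to table indices (3 = missing)."""
        out = np.asarray(g, dtype=np.int64).copy()
        out[out == MISSING] = _MISS_IDX
        return out

    def trio_likelihood(self, offspring, mother, father) -> np.ndarray:
        """Per-locus probability of the observed offspring genotype given
        the observed mother and father genotypes (missing marginalized)."""
        o = self._obs_index(offspring)
        m = self._obs_index(mother)
        f = self._obs_index(father)
        cols = np.arange(self.n_markers)
        joint = self._trio[cols, o, m, f]
        return joint / (self._marg[cols, m] * self._marg[cols, f])

    def population_likelihood(self, offspring, mother) -> np.ndarray:
        """Per-locus probability of the observed offspring genotype given
        the observed mother, the father integrated over Hardy-Weinberg
        population genotypes."""
        o = self._obs_index(offspring)
        m = self._obs_index(mother)
        cols = np.arange(self.n_markers)
        return self._pop[cols, o, m] / self._marg[cols, m]

    def pair_lod(self, offspring, mother, candidate) -> float:
        """Natural-log likelihood ratio summed over loci for one candidate."""
        o = self._obs_index(offspring)
        m = self._obs_index(mother)
        f = self._obs_index(candidate)
        return float(
            self.lod_table[np.arange(self.n_markers), o, m, f].sum()
        )

    def lod_matrix(self, offspring: np.ndarray, mothers: np.ndarray,
                   candidates: np.ndarray) -> np.ndarray:
        """(n_offspring, n_candidates) LOD scores.

        ``offspring`` and ``mothers`` are (n_off, m) call matrices (row i of
        ``mothers`` is the declared mother of offspring i); ``candidates``
        is (n_cand, m).
        """
        o = self._obs_index(offspring)
        mo = self._obs_index(mothers)
        f = self._obs_index(candidates)
        n_off = o.shape[0]
        n_cand = f.shape[0]
        cols = np.arange(self.n_markers)
        out = np.empty((n_off, n_cand))
        for i in range(n_off):
            tab = self.lod_table[cols, o[i], mo[i]]  # (m, 4)
            out[i] = tab[cols[None, :], f].sum(axis=1)
        return out


def genotype_likelihood(observed_offspring, observed_mother, observed_father,
                        freqs, e: float) -> float:
    """Joint probability of a single-locus observed trio under the error
    model; pass ``observed_father="population"`` to integrate the father
    over Hardy-Weinberg genotypes.  Scalar convenience wrapper used in
    tests and small analyses."""
    scorer = PaternityScorer(np.atleast_1d(float(freqs)), e,
                             floor_error=False)
    o = np.atleast_1d(observed_offspring)
    m = np.atleast_1d(observed_mother)
    if isinstance(observed_father, str) and observed_father == "population":
        return float(scorer.population_likelihood(o, m)[0])
    f = np.atleast_1d(observed_father)
    return float(scorer.trio_likelihood(o, m, f)[0])


def pair_lod(offspring, mother, candidate, freqs, cfg: ParentageConfig,
             floor_error: bool = True) -> float:
    """LOD of one candidate father over all loci (natural log)."""
    scorer = PaternityScorer(freqs, cfg.error_rate, floor_error=floor_error)
    return scorer.pair_lod(offspring, mother, candidate)


# ----------------------------------------------------------------------
# Delta calibration
# ----------------------------------------------------------------------


def _sample_hwe_genotypes(rng: np.random.Generator, q: np.ndarray,
                          n: int) -> np.ndarray:
    u = rng.random((n, len(q)))
    p_hom_ref = (1.0 - q) ** 2
    p_not_alt = 1.0 - q**2
    g = np.full((n, len(q)), 2, dtype=np.int8)
    g[u < p_not_alt] = 1
    g[u < p_hom_ref] = 0
    return g


def _mate(rng: np.random.Generator, gm: np.ndarray,
          gf: np.ndarray) -> np.ndarray:
    tm = rng.random(gm.shape) < gm / 2.0
    tf = rng.random(gf.shape) < gf / 2.0
    return (tm.astype(np.int8) + tf.astype(np.int8))


def _corrupt(rng: np.random.Generator, g: np.ndarray, q: np.ndarray,
             e: float) -> np.ndarray:
    if e <= 0:
        return g
    hit = rng.random(g.shape) < e
    repl = _sample_hwe_genotypes(rng, q, g.shape[0])
    out = g.copy()
    out[hit] = repl[hit]
    return out


def _thin(rng: np.random.Generator, g: np.ndarray,
          prop_typed: float) -> np.ndarray:
    if prop_typed >= 1.0:
        return g
    out = g.copy()
    out[rng.random(g.shape) >= prop_typed] = MISSING
    return out


def delta_critical(freqs, cfg: ParentageConfig, seed: int = 0,
                   batch_size: int = 250) -> dict[str, float]:
    """Simulation-calibrated critical Delta per confidence level.

    Simulates ``cfg.n_sim`` offspring whose mother is known and whose true
    father is inside the candidate set with probability ``prop_sampled``
    (otherwise an unsampled male); genotypes are thinned to ``prop_typed``
    and corrupted at the error rate, candidates are scored, and the critical
    Delta for confidence level c is the smallest observed Delta such that
    the assignments exceeding it are correct at proportion >= c.  Returns
    0.0 for a level met by the full assignment set (perfectly separable
    data) and +inf for a level never met.
    """
    q = np.asarray(freqs, dtype=float)
    rng = np.random.default_rng(seed)
    scorer = PaternityScorer(q, cfg.error_rate)
    if cfg.n_sim < 1000:
        warnings.warn(
            f"n_sim={cfg.n_sim} is small; Delta thresholds may be unstable",
            stacklevel=2,
        )
    deltas = np.empty(cfg.n_sim)
    correct = np.empty(cfg.n_sim, dtype=bool)
    done = 0
    while done < cfg.n_sim:
        b = min(batch_size, cfg.n_sim - done)
        cand = _sample_hwe_genotypes(rng, q, cfg.n_candidates)
        cand_obs = _thin(rng, _corrupt(rng, cand, q, cfg.error_rate),
                         cfg.prop_typed)
        mothers = _sample_hwe_genotypes(rng, q, b)
        sampled = rng.random(b) < cfg.prop_sampled
        father_idx = rng.integers(cfg.n_candidates, size=b)
        fathers_true = cand[father_idx]
        unsampled = _sample_hwe_genotypes(rng, q, b)
        fathers_true = np.where(sampled[:, None], fathers_true, unsampled)
        off = _mate(rng, mothers, fathers_true)
        off_obs = _thin(rng, _corrupt(rng, off, q, cfg.error_rate),
                        cfg.prop_typed)
        mo_obs = _thin(rng, _corrupt(rng, mothers, q, cfg.error_rate),
                       cfg.prop_typed)
        lods = scorer.lod_matrix(off_obs, mo_obs, cand_obs)
        order = np.argsort(lods, axis=1)
        best = order[:, -1]
        if cfg.n_candidates >= 2:
            second = lods[np.arange(b), order[:, -2]]
            deltas[done : done + b] = lods[np.arange(b), best] - second
        else:
            deltas[done : done + b] = lods[np.arange(b), best]
        correct[done : done + b] = sampled & (best == father_idx)
        done += b

    order = np.argsort(-deltas, kind="stable")
    sorted_correct = correct[order]
    sorted_deltas = deltas[order]
    cum_rate = np.cumsum(sorted_correct) / np.arange(1, cfg.n_sim + 1)
    thresholds: dict[str, float] = {}
    for name, level in cfg.confidence_levels.items():
        ok = np.nonzero(cum_rate >= level)[0]
        if len(ok) == 0:
            thresholds[name] = np.inf
        else:
            k = ok[-1]  # largest prefix still meeting the level
            thresholds[name] = 0.0 if k == cfg.n_sim - 1 else float(
                sorted_deltas[k]
            )
    return thresholds


# ----------------------------------------------------------------------
# assignment
# ----------------------------------------------------------------------


def assign_paternity(
    offspring: CallMatrix,
    mother_map: pd.Series,
    parents: CallMatrix,
    freqs: pd.Series | np.ndarray,
    cfg: ParentageConfig | None = None,
    thresholds: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Assign a father to every offspring with a declared mother.

    ``mother_map`` maps offspring id -> mother id; mothers must be in the
    parent matrix.  Candidates are all parents except the mother, plus the
    mother herself when ``cfg.test_selfing`` (a winning mother raises the
    selfing flag).  Offspring typed at fewer than ``min_typed_loci`` markers
    are left unassigned.  ``thresholds`` (from :func:`delta_critical`) gate
    the confidence tier; without them every scored offspring is reported at
    the "relaxed" tier.

    Returns a DataFrame indexed by offspring with columns mother, father,
    lod, delta, tier, selfing, n_typed, status.
    """
    cfg = cfg or ParentageConfig()
    if list(offspring.markers.index) != list(parents.markers.index):
        raise ValueError("offspring and parent matrices must share markers")
    scorer = PaternityScorer(np.asarray(freqs, dtype=float), cfg.error_rate)
    parent_lookup = {name: i for i, name in enumerate(parents.individuals)}
    tier_order = sorted(
        cfg.confidence_levels, key=lambda k: cfg.confidence_levels[k],
        reverse=True,
    ) if thresholds else []

    records = []
    n_typed_all = (offspring.genotypes != MISSING).sum(axis=1)
    for i, off_id in enumerate(offspring.individuals):
        mother_id = mother_map.get(off_id)
        if mother_id is None or mother_id not in parent_lookup:
            records.append((off_id, mother_id, None, np.nan, np.nan,
                            "unassigned", False, int(n_typed_all[i]),
                            "no_mother_genotype"))
            continue
        n_typed = int(n_typed_all[i])
        if n_typed < cfg.min_typed_loci:
            records.append((off_id, mother_id, None, np.nan, np.nan,
                            "unassigned", False, n_typed, "too_few_loci"))
            continue
        mi = parent_lookup[mother_id]
        cand_idx = [
            j for j in range(parents.n_individuals)
            if j != mi or cfg.test_selfing
        ]
        cand = parents.genotypes[cand_idx]
        lods = scorer.lod_matrix(
            offspring.genotypes[i : i + 1],
            parents.genotypes[mi : mi + 1],
            cand,
        )[0]
        order = np.argsort(lods)
        best_pos = order[-1]
        best_lod = float(lods[best_pos])
        delta = (
            best_lod - float(lods[order[-2]]) if len(lods) >= 2 else best_lod
        )
        best_id = parents.individuals[cand_idx[best_pos]]
        selfing = best_id == mother_id
        tier = "relaxed"
        if thresholds:
            tier = "unassigned"
            for name in tier_order:
                if delta > thresholds[name]:
                    tier = name
                    break
        father = best_id if tier != "unassigned" else None
        records.append((off_id, mother_id, father, best_lod, delta, tier,
                        selfing and tier != "unassigned", n_typed, "scored"))

    return pd.DataFrame(
        records,
        columns=["offspring", "mother", "father", "lod", "delta", "tier",
                 "selfing", "n_typed", "status"],
    ).set_index("offspring")
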