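"""PSSE orchestration: single-pair and multi-pair estimation.

The estimator for one pair (s1, s2) of lengths (m, n):

1. derive N independent stream seeds from the master seed;
2. produce N permuted copies of the subject s2 (Fisher-Yates, one LCG
   stream per copy);
3. score s1 against the original s2 and against every permuted copy with
   affine-gap Smith-Waterman (the original is scored in the same batch as
   the permutations);
4. fit the N null scores to a left-censored Gumbel;
5. report pss = P(S > x) = 1 - exp(-K*m*n*exp(-lambda*x)) for the observed
   score x.

Multi-pair runs estimate every (query, subject) pair under one of three
batching strategies that differ only in work scheduling, never in results:

- ``intuitive``: the single-pair procedure Q*S times; every subject is
  re-permuted for every query (Q*S*N permutations).
- ``data_reuse``: each subject is permuted once and its copies are reused
  across all queries ("one permutation, all queries": S*N permutations).
- ``tiled``: data reuse within tiles of T subjects, T from the device
  model, so each round's T*N alignments saturate the modeled device
  (S*N permutations).

The seeding contract that makes the three strategies bit-identical: the
permutation seeds for subject index j are draws [j*N, (j+1)*N) of a single
master stream, a function of (master_seed, j, N) only — never of the query
or the strategy.  Subject index 0 therefore uses exactly the single-pair
seed schedule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import align, device_model, evd, rng, scoring
from .seq_io import Sequence

STRATEGIES = ("intuitive", "data_reuse", "tiled")

RESULT_COLUMNS = [
    "query_id",
    "subject_id",
    "score",
    "lambda",
    "K",
    "E_value",
    "pss",
    "N",
    "censored",
    "error",
]


class PsseError(RuntimeError):
    """Pipeline failure; carries the null score sample when fitting failed."""

    def __init__(self, message: str, scores=None):
        super().__init__(message)
        self.scores = scores


@dataclass(frozen=True)
class PsseConfig:
    """Run configuration with the standard defaults (BLOSUM62, 10+2k, N=1000)."""

    n_permutations: int = 1000
    gaps: scoring.GapPenalties = field(default_factory=scoring.GapPenalties)
    matrix: str = "BLOSUM62"
    censor: Union[float, str, None] = "auto"
    master_seed: int = 0
    strategy: str = "data_reuse"
    device: device_model.DeviceModel = field(default_factory=device_model.DeviceModel)

    def __post_init__(self):
        if self.n_permutations < 50:
            raise ValueError(
                f"need N >= 50 permutations for a stable fit, got {self.n_permutations}"
            )
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")


@dataclass(frozen=True)
class PsseResult:
    query_id: str
    subject_id: str
    score: int
    lambda_: float
    K: float
    evalue: float
    pss: float
    n_permutations: int
    n_censored: int
    error: str = ""


@dataclass
class RunCounters:
    """Work accounting, exposed so strategy cost claims are testable."""

    permutations: int = 0
    alignments: int = 0
    fits: int = 0


def subject_permutation_seeds(master_seed: int, subject_index: int, n: int) -> tuple:
    """Seeds for subject j: draws [j*n, (j+1)*n) of the master stream."""
    plan = rng.derive_permutation_seeds(master_seed, (subject_index + 1) * n)
    return plan.seeds[subject_index * n :]


class _Engine:
    """Shared mechanics: profiles, permutation batches, scoring, fitting."""

    def __init__(self, config: PsseConfig):
        self.config = config
        self.matrix = scoring.load_matrix(config.matrix)
        self.counters = RunCounters()
        self._profiles: dict[str, np.ndarray] = {}
        self._overrides: dict[str, scoring.QueryProfile] = {}

    def set_profile(self, query_id: str, profile: scoring.QueryProfile) -> None:
        self._overrides[query_id] = profile

    def profile_for(self, query: Sequence) -> np.ndarray:
        if query.id not in self._profiles:
            override = self._overrides.get(query.id)
            if override is not None:
                if override.length != len(query):
                    raise PsseError(
                        f"PSSM length {override.length} != query {query.id!r} "
                        f"length {len(query)}"
                    )
                slab = override.scores
            else:
                slab = scoring.build_local_profile(query, self.matrix).scores
            self._profiles[query.id] = np.ascontiguousarray(slab)
        return self._profiles[query.id]

    def permutation_batch(self, subject: Sequence, seeds) -> np.ndarray:
        """(N+1, n) uint8 array: row 0 the original subject, rows 1..N copies."""
        codes = subject.codes()
        batch = np.empty((len(seeds) + 1, codes.size), dtype=np.uint8)
        batch[0] = codes
        for i, seed in enumerate(seeds):
            batch[i + 1] = rng.permute_codes(codes, seed)
        self.counters.permutations += len(seeds)
        return batch

    def score_batch(self, query: Sequence, batch: np.ndarray) -> np.ndarray:
        profile = self.profile_for(query)
        lengths = np.full(batch.shape[0], batch.shape[1], dtype=np.int64)
        scores = align.sw_score_codes_batch(
            profile, len(query), batch, lengths, self.config.gaps
        )
        self.counters.alignments += batch.shape[0]
        return scores

    def fit_and_report(self, query: Sequence, subject: Sequence, scores) -> PsseResult:
        observed = int(scores[0])
        null_scores = np.asarray(scores[1:])
        n = self.config.n_permutations
        try:
            fit = evd.fit_censored_evd(
                null_scores,
                censor_value=self.config.censor,
                m=len(query),
                n=len(subject),
            )
            sig = evd.pvalue(observed, fit)
            self.counters.fits += 1
            return PsseResult(
                query_id=query.id,
                subject_id=subject.id,
                score=observed,
                lambda_=fit.lambda_,
                K=fit.K,
                evalue=sig.evalue,
                pss=sig.pvalue,
                n_permutations=n,
                n_censored=fit.n_censored,
            )
        except evd.FitError as exc:
            return PsseResult(
                query_id=query.id,
                subject_id=subject.id,
                score=observed,
                lambda_=math.nan,
                K=math.nan,
                evalue=math.nan,
                pss=math.nan,
                n_permutations=n,
                n_censored=0,
                error=str(exc),
            )


def single_pair_psse(
    s1: Sequence,
    s2: Sequence,
    config: PsseConfig = PsseConfig(),
    profile: Optional[scoring.QueryProfile] = None,
) -> PsseResult:
    """Pairwise statistical significance of one (query, subject) pair.

    Raises :class:`PsseError` (with the null scores attached) when the fit
    fails, e.g. for a degenerate subject whose permutations are all equal.
    """
    engine = _Engine(config)
    if profile is not None:
        engine.set_profile(s1.id, profile)
    seeds = subject_permutation_seeds(config.master_seed, 0, config.n_permutations)
    batch = engine.permutation_batch(s2, seeds)
    scores = engine.score_batch(s1, batch)
    result = engine.fit_and_report(s1, s2, scores)
    if result.error:
        raise PsseError(
            f"fit failed for ({s1.id}, {s2.id}): {result.error}",
            scores=[int(v) for v in scores[1:]],
        )
    return result


def multi_pair_psse(
    queries,
    subjects,
    config: PsseConfig = PsseConfig(),
    profiles: Optional[dict] = None,
    counters: Optional[RunCounters] = None,
) -> pd.DataFrame:
    """Estimate all Q x S pairs; returns a query-major, subject-minor table.

    Per-pair fit failures are recorded in the ``error`` column (with NaN
    statistics) and the run continues.  All three strategies produce
    identical tables for a fixed master seed; pass ``counters`` to observe
    how much work each strategy performed.
    """
    queries = list(queries)
    subjects = list(subjects)
    if not queries or not subjects:
        raise ValueError("need at least one query and one subject")

    engine = _Engine(config)
    for query_id, prof in (profiles or {}).items():
        engine.set_profile(query_id, prof)

    n = config.n_permutations
    # One master stream drives every subject's permutations: subject j owns
    # draws [j*n, (j+1)*n), regardless of query or strategy.
    all_seeds = rng.derive_permutation_seeds(config.master_seed, len(subjects) * n).seeds
    seeds_for = lambda sj: all_seeds[sj * n : (sj + 1) * n]
    results: dict[tuple[int, int], PsseResult] = {}

    if config.strategy == "intuitive":
        for qi, query in enumerate(queries):
            for sj, subject in enumerate(subjects):
                batch = engine.permutation_batch(subject, seeds_for(sj))
                scores = engine.score_batch(query, batch)
                results[(qi, sj)] = engine.fit_and_report(query, subject, scores)
    elif config.strategy == "data_reuse":
        for sj, subject in enumerate(subjects):
            batch = engine.permutation_batch(subject, seeds_for(sj))
            for qi, query in enumerate(queries):
                scores = engine.score_batch(query, batch)
                results[(qi, sj)] = engine.fit_and_report(query, subject, scores)
    else:  # tiled
        for tile in plan_tiled_run(subjects, config):
            batches = []
            for sj in tile:
                batches.append(engine.permutation_batch(subjects[sj], seeds_for(sj)))
            for qi, query in enumerate(queries):
                for sj, batch in zip(tile, batches):
                    scores = engine.score_batch(query, batch)
                    results[(qi, sj)] = engine.fit_and_report(query, subjects[sj], scores)

    if counters is not None:
        counters.permutations = engine.counters.permutations
        counters.alignments = engine.counters.alignments
        counters.fits = engine.counters.fits

    rows = []
    for qi in range(len(queries)):
        for sj in range(len(subjects)):
            r = results[(qi, sj)]
            rows.append(
                (
                    r.query_id,
                    r.subject_id,
                    r.score,
                    r.lambda_,
                    r.K,
                    r.evalue,
                    r.pss,
                    r.n_permutations,
                    r.n_censored,
                    r.error,
                )
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def plan_tiled_run(subjects, config: PsseConfig) -> list[list[int]]:
    """Partition subject indices into tiles of size T from the device model.

    The last tile may be smaller; each tile of size t accounts for t * N
    alignment tasks per query in the modeled round.
    """
    subjects = list(subjects)
    t = device_model.tile_size(config.device, config.n_permutations)
    indices = list(range(len(subjects)))
    return [indices[i : i + t] for i in range(0, len(indices), t)]


def results_tsv(table: pd.DataFrame, config: PsseConfig) -> str:
    """Render the result table as TSV with the configuration echoed as comments."""
    header = [
        f"# matrix={config.matrix}",
        f"# gap_open={config.gaps.open} gap_extend={config.gaps.extend}",
        f"# permutations={config.n_permutations}",
        f"# censor={config.censor}",
        f"# master_seed={config.master_seed}",
        f"# strategy={config.strategy}",
    ]
    body = table.to_csv(sep="\t", index=False)
    return "\n".join(header) + "\n" + body


def with_strategy(config: PsseConfig, strategy: str) -> PsseConfig:
    return replace(config, strategy=strategy)
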