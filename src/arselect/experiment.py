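"""Monte-Carlo harness: conditions x sample sizes x replicates.

For each replicate the harness generates one series, fits all nine
candidates, evaluates the requested selection criteria, and ranks the
candidates per criterion.  Per (condition, T) cell the replicate rankings
are aggregated into the study's three summaries per criterion:

* the mean rank of the true generating model (with its Monte-Carlo SE),
* the proportion of replicates ranking the true model first (with its
  binomial SE, sqrt(p(1-p)/n)),
* the "optimal" model -- the candidate with the smallest mean rank.

Seeding is hierarchical and documented: every replicate's generator and
fitting seeds derive deterministically from (master_seed, condition label,
T, replicate index), so any single cell can be reproduced in isolation.

Cross-validation criteria are computed only for T <= ``cv_max_T`` (default
200) and reported as missing above it; the out-of-sample criterion shares
one population series per condition across replicates by default.
Candidates whose fit fails outright or does not converge are, by default,
ranked after all converged candidates ("rank_last"); the alternative
"drop" policy excludes them from the replicate's ranking.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .dgp import ConditionSpec, condition_registry, generate_series
from .estimators import CANDIDATES, DegenerateSeriesError, EMConfig, fit_candidate
from .selection import ALL_CRITERIA, IC_CRITERIA, CriterionValue, Ranking, ic_value, rank_models
from .validation import CVError, blocked_cv, loo_cv, make_population, oos_mspe

__all__ = [
    "StudyConfig",
    "ReplicateResult",
    "ConditionResult",
    "run_replicate",
    "aggregate",
    "run_study",
    "results_to_frame",
    "rankings_to_frame",
    "render_markdown",
]


@dataclass
class StudyConfig:
    """Configuration of a Monte-Carlo study (defaults = full study design)."""

    conditions: list | None = None          # None -> full registry
    sample_sizes: tuple = (50, 100, 200, 1000)
    n_reps: int = 100
    master_seed: int = 20240
    criteria: tuple = ALL_CRITERIA
    cv_max_T: int = 200                     # CV criteria reported missing above
    cv_blocks: int = 10
    population_size: int = 100_000
    share_population: bool = True           # one population per condition
    nonconverged: str = "rank_last"         # or "drop"
    em_config: EMConfig = field(default_factory=EMConfig)

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.nonconverged not in ("rank_last", "drop"):
            raise ValueError("nonconverged must be 'rank_last' or 'drop'")
        unknown = set(self.criteria) - set(ALL_CRITERIA)
        if unknown:
            raise ValueError(f"unknown criteria {sorted(unknown)}")

    def resolved_conditions(self) -> list:
        return list(self.conditions) if self.conditions is not None else condition_registry()

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "labels" in raw:
            from .dgp import get_condition

            raw["conditions"] = [get_condition(lbl) for lbl in raw.pop("labels")]
        if "em_config" in raw:
            raw["em_config"] = EMConfig(**raw["em_config"])
        for key in ("sample_sizes", "criteria"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _derive_seed(*parts) -> int:
    """Deterministic 31-bit seed from mixed str/int parts."""
    ints = [zlib.crc32(p.encode()) if isinstance(p, str) else int(p) for p in parts]
    ss = np.random.SeedSequence(ints)
    return int(ss.generate_state(1)[0]) % (2**31)


def replicate_seed(master_seed: int, condition: ConditionSpec, T: int, rep: int) -> int:
    """Seed of one replicate; any cell is reproducible in isolation."""
    return _derive_seed(master_seed, condition.label, T, rep)


def population_seed(master_seed: int, condition: ConditionSpec) -> int:
    """Seed of a condition's population series (independent of replicates)."""
    return _derive_seed(master_seed, condition.label, "population")


@dataclass
class ReplicateResult:
    """Per-criterion rankings and bookkeeping for one replicate."""

    condition: ConditionSpec
    T: int
    rep_seed: int
    rankings: dict                 # criterion -> Ranking (absent if not computed)
    values: list                   # all CriterionValue rows (long format)
    nonconverged: list             # candidate names with converged=False
    failed: dict                   # candidate -> error message
    replicate: int | None = None   # replicate index within its cell


@dataclass
class ConditionResult:
    """Aggregated Monte-Carlo summary for one (condition, T) cell."""

    label: str
    model: str
    T: int
    n_reps: int
    criteria: dict                 # criterion -> summary dict
    n_nonconverged: dict           # candidate -> count


def run_replicate(
    condition: ConditionSpec,
    T: int,
    rep_seed: int,
    config: StudyConfig,
    population: np.ndarray | None = None,
    replicate: int | None = None,
) -> ReplicateResult:
    """Generate one series, fit all candidates, and rank them per criterion."""
    ss = np.random.SeedSequence(rep_seed)
    gen_seed, fit_seed = (int(s) % (2**31) for s in ss.generate_state(2))
    series = generate_series(condition, T, gen_seed)
    y = series.values
    true = condition.model

    fits: dict = {}
    failed: dict = {}
    for i, name in enumerate(CANDIDATES):
        try:
            fits[name] = fit_candidate(name, y, seed=fit_seed + i, em_config=config.em_config)
        except DegenerateSeriesError as exc:
            fits[name] = None
            failed[name] = str(exc)
    nonconverged = [n for n, f in fits.items() if f is not None and not f.converged]

    def usable(name):
        f = fits[name]
        if f is None:
            return None
        if not f.converged and config.nonconverged in ("rank_last", "drop"):
            return None
        return f

    def cv_wrap(fn, name, **kw):
        try:
            return fn(name, y, seed=fit_seed, em_config=config.em_config, **kw).cv_value
        except (CVError, DegenerateSeriesError):
            return None

    rankings: dict = {}
    all_values: list = []
    requested = [c for c in ALL_CRITERIA if c in config.criteria]
    cv_available = T <= config.cv_max_T
    for crit in requested:
        values = []
        for name in CANDIDATES:
            f = fits[name]
            p = f.p if f is not None else np.nan
            uf = usable(name)
            val: float | None = None
            if crit in IC_CRITERIA:
                if uf is not None:
                    val = ic_value(crit, uf.loglik, uf.p, uf.T_pred)
            elif crit == "LOOCV":
                if cv_available and uf is not None:
                    val = cv_wrap(loo_cv, name)
            elif crit == "BlockedCV":
                if cv_available and uf is not None:
                    val = cv_wrap(blocked_cv, name, K=config.cv_blocks)
            elif crit == "OOS":
                if uf is not None and population is not None:
                    val = oos_mspe(uf, population)
            values.append(CriterionValue(candidate=name, criterion=crit, value=val, p=p))
        all_values.extend(values)
        if crit in ("LOOCV", "BlockedCV") and not cv_available:
            continue  # emitted as missing ("NA") at this length
        if crit == "OOS" and population is None:
            continue
        if config.nonconverged == "drop":
            values = [v for v in values if not v.missing]
        if all(v.missing for v in values):
            continue
        rankings[crit] = rank_models(values, true_candidate=true, replicate=replicate)
    return ReplicateResult(
        condition=condition,
        T=T,
        rep_seed=rep_seed,
        rankings=rankings,
        values=all_values,
        nonconverged=nonconverged,
        failed=failed,
        replicate=replicate,
    )


def aggregate(replicates: list) -> ConditionResult:
    """Aggregate one cell's replicates into the study's table summaries."""
    if not replicates:
        raise ValueError("no replicates to aggregate")
    cond = replicates[0].condition
    T = replicates[0].T
    n = len(replicates)
    criteria_seen: list = []
    for rep in replicates:
        for c in rep.rankings:
            if c not in criteria_seen:
                criteria_seen.append(c)
    summaries: dict = {}
    for crit in criteria_seen:
        ranks_true = [r.rankings[crit].rank_of_true for r in replicates if crit in r.rankings]
        ranks_true = [r for r in ranks_true if r is not None]
        m = len(ranks_true)
        if m == 0:
            continue
        arr = np.asarray(ranks_true, dtype=float)
        mean_rank = float(arr.mean())
        se_rank = float(arr.std(ddof=1) / np.sqrt(m)) if m > 1 else np.nan
        prop = float(np.mean(arr == 1.0))
        se_prop = float(np.sqrt(prop * (1.0 - prop) / m)) if m > 1 else np.nan
        # mean rank per candidate -> "optimal" model
        cand_ranks: dict = {}
        for rep in replicates:
            rk = rep.rankings.get(crit)
            if rk is None:
                continue
            for name, rank in rk.ranks.items():
                cand_ranks.setdefault(name, []).append(rank)
        means = {name: float(np.mean(v)) for name, v in cand_ranks.items()}
        optimal = min(means, key=lambda k: (means[k], k))
        summaries[crit] = {
            "mean_rank_true": mean_rank,
            "se_rank": se_rank,
            "proportion_correct": prop,
            "se_proportion": se_prop,
            "optimal_model": optimal,
            "optimal_mean_rank": means[optimal],
            "n": m,
        }
    n_nc = {name: 0 for name in CANDIDATES}
    for rep in replicates:
        for name in rep.nonconverged:
            n_nc[name] += 1
        for name in rep.failed:
            n_nc[name] += 1
    return ConditionResult(
        label=cond.label, model=cond.model, T=T, n_reps=n, criteria=summaries, n_nonconverged=n_nc
    )


def run_cell(
    condition: ConditionSpec, T: int, config: StudyConfig, population: np.ndarray | None = None
) -> tuple:
    """All replicates of one (condition, T) cell; returns (result, replicates)."""
    needs_pop = "OOS" in config.criteria
    if needs_pop and population is None:
        population = make_population(
            condition, config.population_size, population_seed(config.master_seed, condition)
        ).values
    reps = []
    for i in range(config.n_reps):
        seed = replicate_seed(config.master_seed, condition, T, i)
        if not config.share_population and needs_pop:
            pop_i = make_population(
                condition, config.population_size, _derive_seed(seed, "population")
            ).values
        else:
            pop_i = population
        reps.append(run_replicate(condition, T, seed, config, population=pop_i, replicate=i))
    return aggregate(reps), reps


def rankings_to_frame(replicates: list) -> pd.DataFrame:
    """Long-format per-replicate table: one row per (candidate, criterion)."""
    rows = []
    for rep in replicates:
        for v in rep.values:
            rk = rep.rankings.get(v.criterion)
            rank = rk.ranks.get(v.candidate) if rk is not None else None
            rows.append(
                {
                    "replicate": rep.replicate if rep.replicate is not None else rep.rep_seed,
                    "condition": rep.condition.label,
                    "T": rep.T,
                    "criterion": v.criterion,
                    "candidate": v.candidate,
                    "value": v.value,
                    "rank": rank,
                }
            )
    return pd.DataFrame(rows)


def results_to_frame(results: list) -> pd.DataFrame:
    """One row per (condition, T, criterion) with the table summaries."""
    rows = []
    for res in results:
        for crit, s in res.criteria.items():
            rows.append(
                {
                    "condition": res.label,
                    "model": res.model,
                    "T": res.T,
                    "criterion": crit,
                    "n_reps": s["n"],
                    "mean_rank_true": s["mean_rank_true"],
                    "se_rank": s["se_rank"],
                    "proportion_correct": s["proportion_correct"],
                    "se_proportion": s["se_proportion"],
                    "optimal_model": s["optimal_model"],
                    "optimal_mean_rank": s["optimal_mean_rank"],
                    "n_nonconverged": json.dumps(res.n_nonconverged, sort_keys=True),
                }
            )
    return pd.DataFrame(rows)


def run_study(config: StudyConfig, out_dir=None) -> list:
    """Iterate conditions x sample sizes; optionally write CSVs incrementally.

    Writes ``rankings.csv`` (long, per replicate) and ``results.csv`` (one
    row per condition x T x criterion) under ``out_dir``.  Partial failures
    inside a cell are recorded, never abort the grid.
    """
    results: list = []
    rankings_path = results_path = None
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rankings_path = out / "rankings.csv"
        results_path = out / "results.csv"
        first = True
    for condition in config.resolved_conditions():
        population = None
        if "OOS" in config.criteria and config.share_population:
            population = make_population(
                condition, config.population_size, population_seed(config.master_seed, condition)
            ).values
        for T in config.sample_sizes:
            result, reps = run_cell(condition, T, config, population=population)
            results.append(result)
            if out_dir is not None:
                rankings_to_frame(reps).to_csv(
                    rankings_path, mode="w" if first else "a", header=first, index=False
                )
                results_to_frame(results).to_csv(results_path, index=False)
                first = False
    return results


def render_markdown(results: list) -> str:
    """Render condition results as Markdown tables in the study layout
    (per condition and sample size: rank / proportion / optimal rows)."""
    lines: list = []
    by_label: dict = {}
    for res in results:
        by_label.setdefault(res.label, []).append(res)
    for label, group in by_label.items():
        group = sorted(group, key=lambda r: r.T)
        crits = [c for c in ALL_CRITERIA if any(c in r.criteria for r in group)]
        lines.append(f"### {label}")
        lines.append("")
        lines.append("| T | Criteria | " + " | ".join(crits) + " |")
        lines.append("|---" * (len(crits) + 2) + "|")
        for res in group:
            def cell(crit, kind):
                s = res.criteria.get(crit)
                if s is None:
                    return "NA (NA)"
                if kind == "rank":
                    return f"{s['mean_rank_true']:.2f} ({s['se_rank']:.2f})"
                if kind == "prop":
                    return f"{s['proportion_correct']:.2f} ({s['se_proportion']:.2f})"
                return f"{s['optimal_model']} ({s['optimal_mean_rank']:.2f})"

            lines.append(f"| {res.T} | Rank | " + " | ".join(cell(c, "rank") for c in crits) + " |")
            lines.append(f"| | Proportion | " + " | ".join(cell(c, "prop") for c in crits) + " |")
            lines.append(f"| | Optimal | " + " | ".join(cell(c, "opt") for c in crits) + " |")
        lines.append("")
    return "\n".join(lines)
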