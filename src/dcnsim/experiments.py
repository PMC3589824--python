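"""End-to-end condition-comparison experiments.

One experiment = generate (or load) a calibrated cohort of soma clouds,
simulate the lateral-inhibition model under each signal-strength
condition with a shared replicate budget, compute anatomy statistics,
and compare conditions with standard hypothesis tests.  Everything is
reproducible from the configuration plus a master seed, and the on-disk
bundle echoes both along with a configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from dcnsim.anatomy_stats import AxonPattern, interaxonal_distances, summarize
from dcnsim.lateral_inhibition import (
    DEFAULT_TIE_DEPTH,
    DEFAULT_TIE_TOLERANCE,
    ModelParams,
    run_replicates,
    summarize_replicates,
)
from dcnsim.synthetic_cluster import GeneratorConfig, SomaCloud, generate_cohort

__all__ = ["ExperimentConfig", "ComparisonResult", "run_experiment", "compare_conditions"]

logger = logging.getLogger("dcnsim.experiments")


@dataclass(frozen=True)
class ExperimentConfig:
    """Full description of a reproducible comparison run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    threshold: float = 0.17
    conditions: tuple[tuple[str, float], ...] = (("control", 1.0), ("notch_lof", 0.1))
    n_clusters: int = 16
    n_reps: int = 100
    seed: int = 0
    tie_tolerance: float = DEFAULT_TIE_TOLERANCE
    tie_depth: float = DEFAULT_TIE_DEPTH
    holm_correction: bool = False

    def __post_init__(self) -> None:
        labels = [label for label, _ in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique")
        if self.n_clusters < 1 or self.n_reps < 1:
            raise ValueError("n_clusters and n_reps must be >= 1")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")

    def config_hash(self) -> str:
        """Stable digest of the serialized configuration."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = dataclasses.asdict(self.generator)
        d["conditions"] = [list(c) for c in self.conditions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "generator" in d and isinstance(d["generator"], dict):
            d["generator"] = GeneratorConfig(**d["generator"])
        if "conditions" in d:
            d["conditions"] = tuple((str(l), float(s)) for l, s in d["conditions"])
        return cls(**d)


@dataclass(frozen=True)
class ComparisonResult:
    """Per-condition summaries plus pairwise test results."""

    summaries: dict
    tests: list[dict]
    config_hash: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "summaries": self.summaries,
            "tests": self.tests,
            "config_hash": self.config_hash,
            "seed": self.seed,
        }


def _condition_seed(master: int, label: str) -> np.random.SeedSequence:
    # label-keyed so permuting the condition list cannot change results
    digest = hashlib.sha256(label.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.SeedSequence([master, key])


def run_condition(
    cohort: list[SomaCloud],
    label: str,
    signal_strength: float,
    config: ExperimentConfig,
) -> tuple[pd.DataFrame, dict]:
    """Replicate table and summary for one signal-strength condition."""
    params = ModelParams(signal_strength=signal_strength)
    table = run_replicates(
        cohort,
        config.threshold,
        params,
        n_reps=config.n_reps,
        seed=_condition_seed(config.seed, label),
        tie_tolerance=config.tie_tolerance,
        tie_depth=config.tie_depth,
    )
    summary = summarize_replicates(table)
    distances = []
    for dv_field in table.loc[table["error"] == "", "winner_dv"]:
        dv = np.array([float(v) for v in dv_field.split(";") if v])
        if len(dv) >= 2:
            pattern = AxonPattern(cluster_id="rep", dv_positions=dv)
            distances.extend(interaxonal_distances(pattern).tolist())
    if len(distances) >= 2:
        block = summarize(distances)
        summary["interaxonal"] = block.as_dict()
    summary["signal_strength"] = signal_strength
    return table, summary


def compare_conditions(
    tables: dict[str, pd.DataFrame],
    test: str = "auto",
    holm: bool = False,
) -> list[dict]:
    """Pairwise tests on axon-count distributions.

    ``test`` is ``"rank-sum"`` (Mann-Whitney U), ``"t"`` (Welch), or
    ``"auto"``: t-test when both samples pass Shapiro-Wilk normality,
    Mann-Whitney otherwise -- mirroring normality-based test selection
    in standard practice.  Conditions with fewer than 3 replicates are
    skipped with a warning entry.  Optional Holm correction across the
    pairwise p-values.
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 conditions to compare")
    labels = list(tables)
    results: list[dict] = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            la, lb = labels[i], labels[j]
            a = tables[la]["axon_count"].dropna().to_numpy(dtype=float)
            b = tables[lb]["axon_count"].dropna().to_numpy(dtype=float)
            if len(a) < 3 or len(b) < 3:
                logger.warning("skipping %s vs %s: < 3 replicates", la, lb)
                results.append(
                    {"pair": [la, lb], "skipped": True, "reason": "< 3 replicates"}
                )
                continue
            chosen = test
            if test == "auto":
                normal = all(
                    np.std(x) > 0 and stats.shapiro(x).pvalue > 0.05 for x in (a, b)
                )
                chosen = "t" if normal else "rank-sum"
            if chosen == "t":
                res = stats.ttest_ind(a, b, equal_var=False)
                stat_name = "welch_t"
            elif chosen == "rank-sum":
                res = stats.mannwhitneyu(a, b, alternative="two-sided")
                stat_name = "mann_whitney_u"
            else:
                raise ValueError(f"unknown test {test!r}")
            results.append(
                {
                    "pair": [la, lb],
                    "skipped": False,
                    "test": stat_name,
                    "statistic": float(res.statistic),
                    "p_value": float(res.pvalue),
                    "mean_difference": float(np.mean(a) - np.mean(b)),
                }
            )
    if holm:
        done = [r for r in results if not r.get("skipped")]
        order = np.argsort([r["p_value"] for r in done])
        m = len(done)
        adjusted = {}
        running = 0.0
        for rank, idx in enumerate(order):
            adj = min(1.0, (m - rank) * done[idx]["p_value"])
            running = max(running, adj)
            adjusted[idx] = running
        for idx, r in enumerate(done):
            r["p_value_holm"] = adjusted[idx]
    return results


def run_experiment(
    config: ExperimentConfig,
    out_dir: str | Path | None = None,
    cohort: list[SomaCloud] | None = None,
    test: str = "auto",
) -> ComparisonResult:
    """Full pipeline: cohort -> replicates per condition -> comparison.

    If ``out_dir`` is given, writes the reproducibility bundle:
    ``config.json`` (echo with hash and seed), one
    ``replicates_<label>.csv`` per condition, ``summary.json``,
    ``comparison.json`` and a plain-text run log under ``logs/``.
    """
    t0 = time.time()
    if cohort is None:
        cohort = generate_cohort(
            config.generator,
            config.n_clusters,
            np.random.SeedSequence([config.seed, 0xC040]),  # cohort stream
        )
    tables: dict[str, pd.DataFrame] = {}
    summaries: dict[str, dict] = {}
    log_lines = [f"config_hash={config.config_hash()} seed={config.seed}"]
    for label, strength in config.conditions:
        table, summary = run_condition(cohort, label, strength, config)
        n_failed = summary["n_failed"]
        total = len(table)
        if n_failed > 0.10 * total:
            raise RuntimeError(
                f"condition {label!r}: {n_failed}/{total} replicates failed"
            )
        tables[label] = table
        summaries[label] = summary
        log_lines.append(
            f"condition={label} s={strength} mean={summary['mean_axon_count']:.3f} "
            f"sd={summary['sd_axon_count']:.3f} n={summary['n']}"
        )
    tests = (
        compare_conditions(tables, test=test, holm=config.holm_correction)
        if len(tables) >= 2
        else []
    )
    result = ComparisonResult(
        summaries=summaries,
        tests=tests,
        config_hash=config.config_hash(),
        seed=config.seed,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "logs").mkdir(exist_ok=True)
        with open(out / "config.json", "w") as fh:
            json.dump(
                {"config": config.to_dict(), "config_hash": config.config_hash()},
                fh,
                indent=2,
            )
        for label, table in tables.items():
            table.to_csv(out / f"replicates_{label}.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summaries, fh, indent=2)
        with open(out / "comparison.json", "w") as fh:
            json.dump(result.to_dict(), fh, indent=2)
        log_lines.append(f"elapsed_s={time.time() - t0:.1f}")
        (out / "logs" / "run.log").write_text("\n".join(log_lines) + "\n")
    return result
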