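"""Pipeline orchestration: run all analyses from one configuration.

A :class:`RunConfig` names the input cohort (or a synthetic/pseudo-cohort
source), which analyses to run, per-analysis parameter blocks and seeds.
:func:`run_pipeline` executes the toggled analyses in order (single-locus →
haplotype → G-score → MDR → CART), writes one delimited report per analysis
in the layout of the corresponding published table, one machine-readable
``results.json``, and a plain-text run log recording seeds, exclusion
counts and parameters.  Identical config + seeds produce byte-identical
machine-readable output.  Subgroup (e.g. gender-stratified) reruns filter
the cohort on a covariate predicate first.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

from . import study
from .cart import CartParams, GenotypeTree
from .cohort import Cohort, load_cohort, write_cohort
from .gscore import GenotypeScore
from .haplotype import HaplotypeEM
from .mdr import Mdr
from .simulate import simulate_cohort
from .single_locus import SingleLocusScan

logger = logging.getLogger(__name__)

ANALYSES = ("single_locus", "haplotype", "gscore", "mdr", "cart")


class PipelineError(RuntimeError):
    """An analysis failed; carries the module name and config key."""

    def __init__(self, module: str, key: str, cause: Exception):
        super().__init__(f"[{module}] (config key {key!r}): {cause}")
        self.module = module
        self.key = key
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``source`` selects the cohort: ``{"kind": "file", "path": ..., "format":
    ..., "manifest": ...}``, ``{"kind": "study_pseudo"}`` (pseudo-cohort from
    the built-in printed tables) or ``{"kind": "study_synthetic"}``
    (retrospective simulation from the built-in study spec).
    """

    source: Mapping = field(default_factory=lambda: {"kind": "study_pseudo"})
    analyses: tuple[str, ...] = ("single_locus", "gscore")
    out_dir: str | Path = "results"
    seed: int = 0
    subgroup: str | None = None          # e.g. "sex == 'female'"
    covariates: tuple[str, ...] = ()
    params: Mapping[str, Mapping] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.analyses:
            raise ValueError("at least one analysis must be toggled on")
        unknown = set(self.analyses) - set(ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses {sorted(unknown)}; "
                             f"choose from {ANALYSES}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                kwargs[f.name] = raw[f.name]
        if "analyses" in kwargs:
            kwargs["analyses"] = tuple(kwargs["analyses"])
        if "covariates" in kwargs:
            kwargs["covariates"] = tuple(kwargs["covariates"])
        return cls(**kwargs)


def _load_source(config: RunConfig) -> Cohort:
    src = dict(config.source)
    kind = src.get("kind", "file")
    if kind == "file":
        return load_cohort(src["path"], src.get("format", "delimited"),
                           src["manifest"])
    if kind == "study_pseudo":
        return study.pseudo_cohort(src.get("collapsed_mode", "het"))
    if kind == "study_synthetic":
        return simulate_cohort(study.cohort_spec(seed=config.seed))
    raise ValueError(f"unknown cohort source kind {kind!r}")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def run_pipeline(config: RunConfig,
                 subgroup_filter: Callable[[Cohort], np.ndarray] | None = None
                 ) -> dict:
    """Execute the toggled analyses; returns the machine-readable results
    dict (also written to ``<out_dir>/results.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"seed={config.seed}",
                            f"analyses={','.join(config.analyses)}"]
    cohort = _load_source(config)
    label = "all"
    if subgroup_filter is not None:
        mask = np.asarray(subgroup_filter(cohort), dtype=bool)
        if not mask.any():
            raise ValueError("subgroup filter selects no individuals")
        cohort = cohort.subset(mask)
        label = "subgroup"
        log_lines.append(f"subgroup_n={cohort.n}")
    log_lines.append(f"n_case={cohort.n_case} n_control={cohort.n_control}")

    results: dict = {"seed": config.seed, "subgroup": label,
                     "n_case": cohort.n_case, "n_control": cohort.n_control,
                     "analyses": {}}
    failures: dict[str, str] = {}

    for name in config.analyses:
        p = dict(config.params.get(name, {}))
        try:
            if name == "single_locus":
                res = SingleLocusScan(cohort, covariates=config.covariates).fit(
                    mcs_reps=int(p.get("mcs_reps", 10_000)), seed=config.seed)
                res.to_tsv(out / f"single_locus_{label}.tsv")
                df = res.summary()
                results["analyses"]["single_locus"] = df.to_dict(orient="records")
            elif name == "haplotype":
                systems = p.get("systems")
                if systems is None:
                    systems = [list(pair) for pair in study.LD_PAIRS]
                blocks = {}
                for snp_ids in systems:
                    r = HaplotypeEM(cohort, snp_ids).fit(
                        min_freq=float(p.get("min_freq", 0.01)))
                    key = "+".join(snp_ids)
                    r.summary().to_csv(out / f"haplotype_{key}_{label}.tsv",
                                       sep="\t", index=False)
                    blocks[key] = {
                        "frequencies_case": dict(zip(r.case.haplotypes,
                                                     r.case.frequencies)),
                        "frequencies_control": dict(zip(r.control.haplotypes,
                                                        r.control.frequencies)),
                        "global_p": r.assoc.global_p,
                        "D_prime": None if r.ld is None else r.ld.D_prime,
                    }
                results["analyses"]["haplotype"] = blocks
            elif name == "gscore":
                res = GenotypeScore(cohort, covariates=config.covariates,
                                    direction=p.get("direction", "variant")).fit()
                res.summary().to_csv(out / f"gscore_{label}.tsv", sep="\t",
                                     index=False)
                s = res.overall
                results["analyses"]["gscore"] = {
                    "mean_case": s.mean_case, "sd_case": s.sd_case,
                    "mean_control": s.mean_control, "sd_control": s.sd_control,
                    "p_value": s.p_value, "n_excluded": res.n_excluded,
                    "per_allele_or": res.per_allele["odds_ratio"],
                }
                log_lines.append(f"gscore_excluded={res.n_excluded}")
            elif name == "mdr":
                res = Mdr(cohort,
                          orders=tuple(p.get("orders", (1, 2, 3, 4))),
                          folds=int(p.get("folds", 10))).fit(
                    seed=config.seed, n_perm=int(p.get("permutations", 1000)))
                res.to_tsv(out / f"mdr_{label}.tsv")
                results["analyses"]["mdr"] = {
                    str(o): {"loci": list(m.loci), "testing_accuracy": m.test_acc,
                             "cvc": m.cvc, "perm_p": m.perm_p}
                    for o, m in res.best.items()}
            elif name == "cart":
                cp = CartParams(
                    min_parent=int(p.get("min_parent", 20)),
                    min_child=int(p.get("min_child", 7)),
                    max_depth=int(p.get("max_depth", 5)),
                    min_gini_gain=float(p.get("min_gini_gain", 1e-4)))
                res = GenotypeTree(cohort, params=cp,
                                   covariates=config.covariates).fit()
                res.summary().to_csv(out / f"cart_{label}.tsv", sep="\t",
                                     index=False)
                results["analyses"]["cart"] = {
                    "n_terminal": len(res.tree.terminal_nodes),
                    "split_snps": sorted(res.tree.split_snps()),
                    "terminal": res.terminal_summary().to_dict(orient="records"),
                }
        except Exception as exc:  # surfaced with module and config key
            failures[name] = str(exc)
            logger.error("analysis %s failed: %s", name, exc)

    if failures:
        results["failures"] = failures
        (out / "FAILURES.json").write_text(
            json.dumps(failures, indent=2, sort_keys=True) + "\n")
    (out / f"results_{label}.json").write_text(
        json.dumps(results, indent=2, sort_keys=True, default=_json_default)
        + "\n")
    (out / f"run_{label}.log").write_text("\n".join(log_lines) + "\n")
    if failures:
        raise PipelineError(next(iter(failures)), next(iter(failures)),
                            RuntimeError(failures[next(iter(failures))]))
    return results


def subgroup_run(config: RunConfig, column: str, value: str) -> dict:
    """Re-run the pipeline on the subgroup where covariate ``column`` equals
    ``value`` (e.g. sex == female)."""

    def flt(cohort: Cohort) -> np.ndarray:
        if cohort.covariates is None or column not in cohort.covariates:
            raise ValueError(f"covariate {column!r} not present")
        return (cohort.covariates[column] == value).to_numpy()

    return run_pipeline(config, subgroup_filter=flt)
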