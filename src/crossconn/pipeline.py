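"""End-to-end study pipeline and its configuration.

``run_pipeline`` ties the stages together on a study directory: functional
connectivity per session, whole-brain rDCM effective connectivity, paired
mass-univariate tests with FDR over the FC / EC / self-connection families,
the directed-asymmetry analysis, task and behavioural PLSC on residualized
features, and random-forest condition decoding for FC and EC with a McNemar
comparison. Outputs land in a deterministic directory layout with a
machine-readable ``summary.json``; everything is reproducible from
(config, seed, input files) — the global seed fans out to per-stage child
seeds through ``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import crossval_rf, mcnemar_compare, permutation_test_bac
from .connectivity import ec_feature_table, fc_feature_table
from .datatypes import CONDITIONS
from .group_stats import COVARIATE_COLUMNS, asymmetry_tests, paired_tests_fdr, residualize
from .io import read_study, write_matrix_tsv
from .plsc import behavioural_plsc, select_behavioural_features, task_plsc
from .rdcm import RdcmPrior, invert_rdcm
from .simulate import SimulationConfig

SUMMARY_SCHEMA_VERSION = 1
#: fixed order in which stage child seeds are drawn from the global seed
STAGE_SEED_ORDER = ("simulate", "rdcm", "stats", "plsc", "classify")


def _block(cls):
    cls.__block__ = True
    return cls


@_block
@dataclass
class RdcmBlock:
    fmax: float | None = None
    whiten_hrf: bool = True
    rolloff: float = 0.8
    mean_offdiag: float = 0.0
    var_offdiag: float = 1.0
    mean_self: float = -0.5
    var_self: float = 0.25
    tau_shape: float = 2.0
    tau_rate: float = 1.0
    normalize: bool = True

    def prior(self) -> RdcmPrior:
        return RdcmPrior(self.mean_offdiag, self.var_offdiag, self.mean_self,
                         self.var_self, self.tau_shape, self.tau_rate)


@_block
@dataclass
class PlscBlock:
    n_perm: int = 2000
    n_boot: int = 2000
    behavioural_mode: str = "drug"  # or "difference"


@_block
@dataclass
class ClassifyBlock:
    k: int = 5
    n_trees: int = 500
    n_perm: int = 1000
    perm_n_trees: int = 100  # lighter forests inside the permutation null
    var_tol: float = 1e-10
    corr_tol: float = 0.95


@_block
@dataclass
class StatsBlock:
    alpha: float = 0.05
    asymmetry_fdr: bool = False


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, grouped per stage; unknown keys reject."""

    seed: int = 0
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    rdcm: RdcmBlock = field(default_factory=RdcmBlock)
    plsc: PlscBlock = field(default_factory=PlscBlock)
    classify: ClassifyBlock = field(default_factory=ClassifyBlock)
    stats: StatsBlock = field(default_factory=StatsBlock)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls()
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" in raw:
            cfg.seed = int(raw["seed"])
        for f in dataclasses.fields(cls):
            if f.name == "seed" or f.name not in raw:
                continue
            block_cls = type(getattr(cfg, f.name))
            block_fields = {bf.name for bf in dataclasses.fields(block_cls)}
            bad = set(raw[f.name]) - block_fields
            if bad:
                raise ValueError(f"unknown keys in config block {f.name!r}: {sorted(bad)}")
            setattr(cfg, f.name, block_cls(**raw[f.name]))
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def stage_seeds(seed: int) -> dict[str, np.random.SeedSequence]:
    """Deterministic per-stage child seeds from the single global seed."""
    children = np.random.SeedSequence(seed).spawn(len(STAGE_SEED_ORDER))
    return dict(zip(STAGE_SEED_ORDER, children))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_json_default))


def run_pipeline(config: PipelineConfig, manifest_path: Path, out_dir: Path) -> Path:
    """Run the full analysis on a study directory; returns the summary path.

    Stage failures abort with the failing stage named; outputs of earlier
    stages are retained in ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
    }
    stage = "load"
    try:
        sessions, covariates, behaviour = read_study(Path(manifest_path))
        labels = sessions[0].region_labels
        summary["n_sessions"] = len(sessions)
        summary["n_regions"] = len(labels)

        stage = "fc"
        fc_dir = out_dir / "fc"
        fc_dir.mkdir(exist_ok=True)
        fc_features = fc_feature_table(sessions)
        fc_features.to_csv(fc_dir / "fc_features.csv", float_format="%.10g")

        stage = "rdcm"
        ec_dir = out_dir / "ec"
        ec_dir.mkdir(exist_ok=True)
        prior = config.rdcm.prior()
        connectomes = [
            invert_rdcm(ts, prior, fmax=config.rdcm.fmax,
                        whiten_hrf=config.rdcm.whiten_hrf,
                        rolloff=config.rdcm.rolloff,
                        normalize=config.rdcm.normalize)
            for ts in sessions
        ]
        for ec in connectomes:
            write_matrix_tsv(ec.a, labels, ec_dir / f"{ec.subject_id}_{ec.condition}_A.tsv")
        ec_features = ec_feature_table(connectomes, "ec_full")
        self_features = ec_feature_table(connectomes, "ec_self")
        ec_features.to_csv(ec_dir / "ec_features.csv", float_format="%.10g")

        stage = "stats"
        stats_dir = out_dir / "stats"
        stats_dir.mkdir(exist_ok=True)
        summary["mass_univariate"] = {}
        for name, table in (("fc", fc_features), ("ec", ec_features),
                            ("ec_self", self_features)):
            a = table.xs("drug", level="condition")
            b = table.xs("placebo", level="condition").loc[a.index]
            res = paired_tests_fdr(a, b, alpha=config.stats.alpha)
            res.to_frame().to_csv(stats_dir / f"paired_{name}.csv", float_format="%.10g")
            summary["mass_univariate"][name] = {
                "n_features": len(res.feature_ids),
                "n_significant_fdr": res.n_significant,
            }

        stage = "asymmetry"
        asym_dir = out_dir / "asymmetry"
        asym_dir.mkdir(exist_ok=True)
        by_cond = {c: {} for c in CONDITIONS}
        for ec in connectomes:
            by_cond[ec.condition][ec.subject_id] = ec.a
        asym = asymmetry_tests(by_cond["drug"], by_cond["placebo"], labels,
                               alpha=config.stats.alpha, fdr=config.stats.asymmetry_fdr)
        pd.DataFrame(
            {
                "t_drug": asym.t_drug, "p_drug": asym.p_drug,
                "t_placebo": asym.t_placebo, "p_placebo": asym.p_placebo,
                "t_interaction": asym.t_interaction,
                "p_interaction": asym.p_interaction,
            },
            index=pd.Index([f"{a}|{b}" for a, b in asym.pairs], name="pair"),
        ).to_csv(asym_dir / "asymmetry.csv", float_format="%.10g")
        summary["asymmetry"] = asym.counts

        stage = "plsc"
        plsc_dir = out_dir / "plsc"
        plsc_dir.mkdir(exist_ok=True)
        rng_plsc = np.random.default_rng(seeds["plsc"])
        summary["plsc"] = {}
        for name, table in (("fc", fc_features), ("ec", ec_features),
                            ("ec_self", self_features)):
            resid = residualize(table, covariates)
            task = task_plsc(resid, n_perm=config.plsc.n_perm,
                             n_boot=config.plsc.n_boot, seed=rng_plsc)
            behav_feats = select_behavioural_features(
                resid, config.plsc.behavioural_mode
            )
            behav = behavioural_plsc(behav_feats, behaviour,
                                     n_perm=config.plsc.n_perm,
                                     n_boot=config.plsc.n_boot, seed=rng_plsc)
            pd.DataFrame(
                task.bootstrap_ratios,
                index=pd.Index(task.feature_ids, name="feature_id"),
                columns=[f"LV{i + 1}" for i in range(task.saliences.shape[1])],
            ).to_csv(plsc_dir / f"task_bsr_{name}.csv", float_format="%.10g")
            summary["plsc"][name] = {
                "task_singular_values": task.singular_values,
                "task_perm_p": task.perm_p,
                "behavioural_perm_p": float(behav.perm_p[0]),
                "behavioural_latent_r": behav.behav_correlation,
            }

        stage = "classify"
        cls_dir = out_dir / "classify"
        cls_dir.mkdir(exist_ok=True)
        rng_cls = np.random.default_rng(seeds["classify"])
        y = np.array([ts.condition for ts in sessions])
        groups = np.array([ts.subject_id for ts in sessions])
        cov = covariates.loc[groups, COVARIATE_COLUMNS].to_numpy(float)
        summary["classify"] = {}
        reports = {}
        for name, table in (("fc", fc_features), ("ec", ec_features)):
            x = table.to_numpy(float)
            row_order = [
                table.index.get_loc((s, c)) for s, c in zip(groups, y)
            ]
            x = x[row_order]
            cv_seed = int(rng_cls.integers(2**31 - 1))
            report = crossval_rf(
                x, y, groups, covariates=cov, k=config.classify.k,
                n_trees=config.classify.n_trees, var_tol=config.classify.var_tol,
                corr_tol=config.classify.corr_tol, seed=cv_seed,
            )

            def rerun(perm_labels, _x=x, _seed=cv_seed):
                return crossval_rf(
                    _x, perm_labels, groups, covariates=cov,
                    k=config.classify.k, n_trees=config.classify.perm_n_trees,
                    var_tol=config.classify.var_tol,
                    corr_tol=config.classify.corr_tol, seed=_seed,
                ).bac

            if config.classify.n_perm:
                null, p = permutation_test_bac(
                    rerun, y, groups, report.bac,
                    n_perm=config.classify.n_perm, seed=rng_cls,
                )
                report.perm_null, report.perm_p = null, p
            reports[name] = report
            summary["classify"][name] = {
                "bac": report.bac,
                "perm_p": report.perm_p,
            }
        stat, p = mcnemar_compare(reports["fc"].y_pred, reports["ec"].y_pred, y)
        summary["classify"]["mcnemar_fc_vs_ec"] = {"statistic": stat, "p": p}
        _write_json(
            {k: {"bac": r.bac, "perm_p": r.perm_p,
                 "y_pred": r.y_pred, "y_true": r.y_true} for k, r in reports.items()},
            cls_dir / "reports.json",
        )
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    _write_json(summary, out_dir / "summary.json")
    _write_json(
        {
            "config": config.to_dict(),
            "seed": config.seed,
            "versions": {
                "crossconn": __version__,
                "python": sys.version.split()[0],
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        },
        out_dir / "run_log.json",
    )
    return out_dir / "summary.json"
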