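"""End-to-end study orchestration.

``run_study`` reproduces the full analysis design: generate (or load) a
learning and a testing cohort, restrict to elective procedures, score every
record with the three stratifiers (MCRS, Wu, TSPC), derive Wu cutpoints on
the learning set, fit zero-truncated NB models per stratifier on the
testing set with provider-clustered variance, compare the fits with the
nonnested test, assess extended-LOS discrimination, and optionally re-grow
a prognostic tree from the learning set's complication endpoint and check
its partition against the fixed TSPC rule.

The learning/testing split of the original registry was temporal; the
synthetic analogue is two independent generator draws with identical
parameters, preserving the derive-then-validate discipline.  All outputs
are deterministic under the study seed (named substreams per stage), and
report files contain no timestamps, so a repeated run is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import pcilos
from pcilos import compare, discrimination, registry, risk_scores, tree, ztnb
from pcilos.schema import COHORT_COLUMNS, SchemaError, validate_cohort

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "run_study", "load_cohort"]


@dataclass
class StudyConfig:
    """Configuration of a full study run.

    ``n_learning``/``n_testing`` default to the registry's published
    cohort sizes; ``reduced=True`` swaps in 20,000/20,000 for quick runs.
    ``generator_overrides`` are applied to both cohorts' generator configs.
    """

    seed: int = 20110718
    n_learning: int = 67_766
    n_testing: int = 79_545
    reduced: bool = False
    out_dir: str | None = None
    generator_overrides: dict = field(default_factory=dict)
    folds: int = 10
    tree_min_leaf: int = 200
    tree_max_depth: int | None = 6
    cv_rule: str = "one_se"
    grow_tree: bool = True
    write_cohorts: bool = False
    cutpoint_objective: str = "ztnb"

    def sizes(self) -> tuple[int, int]:
        if self.reduced:
            return 20_000, 20_000
        return self.n_learning, self.n_testing


def load_cohort(path: str | Path) -> pd.DataFrame:
    """Load and validate a cohort CSV.

    Schema violations are reported with row numbers; unknown extra columns
    are preserved and logged as a warning.
    """
    df = pd.read_csv(path)
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    if extra:
        logger.warning("load_cohort: ignoring %d unknown columns %s", len(extra), extra)
    validate_cohort(df, context=str(path))
    return df


def _round(x: float, nd: int) -> float:
    return float(np.round(x, nd))


def _seeded_generator_config(cfg: StudyConfig, n: int, stream: int) -> registry.GeneratorConfig:
    kwargs = dict(cfg.generator_overrides)
    kwargs.setdefault("n", n)
    kwargs.setdefault(
        "seed", int(np.random.SeedSequence([cfg.seed, stream]).generate_state(1)[0] % (2**31))
    )
    return registry.GeneratorConfig(**kwargs)


def _score_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    out = cohort.copy()
    out["mcrs_score"] = risk_scores.mcrs_score_frame(cohort, elective_mode=True)
    out["mcrs_cat"] = risk_scores.MCRS_CUTPOINTS.assign(out["mcrs_score"])
    out["wu_score"] = risk_scores.wu_score_frame(cohort)
    out["wu_cat"] = risk_scores.WU_CUTPOINTS.assign(out["wu_score"])
    out["tspc_cat"] = tree.tspc_classify(cohort)
    return out


def _stratifier_tables(fit: ztnb.ZTNBFit, cats: pd.Categorical) -> dict:
    rr = ztnb.relative_risks(fit)
    cm = ztnb.conditional_means(fit)
    n = len(cats)
    table = []
    for _, row in rr.iterrows():
        lev = row["category"]
        cmrow = cm.loc[cm["category"] == lev].iloc[0]
        table.append(
            {
                "category": lev,
                "share_pct": _round(100.0 * (pd.Categorical(cats) == lev).sum() / n, 1),
                "rr": _round(row["rr"], 2),
                "rr_ci": [_round(row["ci_lo"], 2), _round(row["ci_hi"], 2)],
                "conditional_mean_los": _round(cmrow["conditional_mean"], 1),
            }
        )
    return {
        "rows": table,
        "loglik": _round(fit.loglik_total, 2),
        "alpha": _round(fit.alpha, 4),
        "n": fit.n,
    }


def run_study(config: StudyConfig) -> dict:
    """Run the full study; returns the manifest/report bundle as a dict.

    If ``config.out_dir`` is set, writes ``report.json``, ``tables.md``,
    ``manifest.json`` and (optionally) the cohort CSVs there.
    """
    n_learning, n_testing = config.sizes()
    manifest: dict = {
        "package_version": pcilos.__version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
        "outputs": [],
    }
    stage = "generate"
    try:
        gen_learning = _seeded_generator_config(config, n_learning, 1)
        gen_testing = _seeded_generator_config(config, n_testing, 2)
        learning = registry.generate_cohort(gen_learning)
        testing = registry.generate_cohort(gen_testing)
        manifest["stages"]["generate"] = {
            "n_learning": len(learning),
            "n_testing": len(testing),
        }

        stage = "elective_filter"
        learning, counts_l = risk_scores.elective_filter(learning, return_counts=True)
        testing, counts_t = risk_scores.elective_filter(testing, return_counts=True)
        manifest["stages"]["elective_filter"] = {
            "learning_exclusions": counts_l,
            "testing_exclusions": counts_t,
            "n_learning": len(learning),
            "n_testing": len(testing),
        }

        stage = "score"
        learning = _score_cohort(learning)
        testing = _score_cohort(testing)

        stage = "cutpoint_search"
        derived = risk_scores.cutpoint_search(
            learning["wu_score"].to_numpy(),
            learning["los_days"].to_numpy(),
            objective=config.cutpoint_objective,
        )
        manifest["stages"]["cutpoint_search"] = {
            "derived_wu_cutpoints": list(derived.uppers),
            "published_wu_cutpoints": list(risk_scores.WU_CUTPOINTS.uppers),
            "objective": config.cutpoint_objective,
        }

        stage = "fit"
        clusters = testing["provider_id"].to_numpy()
        los = testing["los_days"].to_numpy()
        fits = {
            name: ztnb.fit_ztnb_categories(testing[col], los, cluster_ids=clusters)
            for name, col in (("mcrs", "mcrs_cat"), ("wu", "wu_cat"), ("tspc", "tspc_cat"))
        }
        report_tables = {
            name: _stratifier_tables(fit, testing[col])
            for (name, col), fit in zip(
                (("mcrs", "mcrs_cat"), ("wu", "wu_cat"), ("tspc", "tspc_cat")), fits.values()
            )
        }

        stage = "compare"
        ll_table = compare.loglik_report(fits)
        comparisons = {}
        for a, b in (("mcrs", "wu"), ("tspc", "wu")):
            plain = compare.vuong_test(fits[a].loglik_per_obs, fits[b].loglik_per_obs)
            clustered = compare.vuong_test(
                fits[a].loglik_per_obs, fits[b].loglik_per_obs, cluster_ids=clusters
            )
            comparisons[f"{a}_vs_{b}"] = {
                "z": _round(plain.z_statistic, 3),
                "p": _round(plain.p_value, 4),
                "favors": b if plain.direction == "B" else (a if plain.direction == "A" else "none"),
                "z_clustered": _round(clustered.z_statistic, 3),
                "p_clustered": _round(clustered.p_value, 4),
            }

        stage = "discriminate"
        ext = discrimination.extended_los(los)
        aucs = {}
        for name, col, ordinal in (
            ("mcrs", "mcrs_cat", testing["mcrs_score"]),
            ("wu", "wu_cat", testing["wu_score"]),
            ("tspc", "tspc_cat", pd.Categorical(testing["tspc_cat"]).codes),
        ):
            res = discrimination.c_statistic(np.asarray(ordinal, float), ext, model=name)
            aucs[name] = {
                "auc": _round(res.auc, 3),
                "ci": [_round(res.ci_lo, 3), _round(res.ci_hi, 3)],
            }
        p_tspc = discrimination.category_probabilities(testing["tspc_cat"], ext)
        p_wu = discrimination.category_probabilities(testing["wu_cat"], ext)
        idi_res = discrimination.idi(p_wu, p_tspc, ext)
        idi_summary = {
            "idi_wu_over_tspc": _round(idi_res.idi, 4),
            "ci": [_round(idi_res.ci_lo, 4), _round(idi_res.ci_hi, 4)],
        }

        grown_summary = None
        if config.grow_tree:
            stage = "grow_tree"
            Xl = tree.tspc_design_matrix(learning)
            grown, seq = tree.cv_select(
                Xl,
                learning["complication"].to_numpy(),
                folds=config.folds,
                rule=config.cv_rule,
                seed=int(np.random.SeedSequence([config.seed, 3]).generate_state(1)[0] % (2**31)),
                min_leaf=config.tree_min_leaf,
                max_depth=config.tree_max_depth,
            )
            Xt = tree.tspc_design_matrix(testing)
            grown_labels = grown.classify(Xt)
            agree = tree.same_partition(grown_labels, np.asarray(testing["tspc_cat"], dtype=object))
            grown_summary = {
                "n_leaves": grown.n_leaves,
                "matches_published_partition": bool(agree),
                "cv_alphas": [float(a) for a in seq.alphas],
                "render": grown.render(),
            }

        report = {
            "stratification": report_tables,
            "loglik": ll_table.to_dict(orient="records"),
            "nonnested_tests": comparisons,
            "discrimination": {"auc": aucs, "idi": idi_summary},
            "grown_tree": grown_summary,
        }
        manifest["stages"]["fit"] = {name: report_tables[name]["loglik"] for name in fits}
        manifest["report"] = report

        if config.out_dir is not None:
            stage = "write"
            out_dir = Path(config.out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            paths = {
                "report.json": json.dumps(report, indent=2, sort_keys=True),
                "tables.md": _render_tables_md(report),
            }
            if config.write_cohorts:
                registry.write_cohort(learning, out_dir / "learning.csv", gen_learning)
                registry.write_cohort(testing, out_dir / "testing.csv", gen_testing)
                manifest["outputs"] += ["learning.csv", "testing.csv"]
            for name, text in paths.items():
                (out_dir / name).write_text(text)
                manifest["outputs"].append(name)
            manifest["outputs"].append("manifest.json")
            (out_dir / "manifest.json").write_text(
                json.dumps(manifest, indent=2, sort_keys=True, default=str)
            )
            for name in manifest["outputs"]:
                assert (out_dir / name).exists()
    except Exception as exc:
        raise RuntimeError(
            f"study aborted at stage {stage!r}: {exc} "
            f"(manifest so far: {json.dumps(manifest['stages'], default=str)})"
        ) from exc
    return manifest


def _render_tables_md(report: dict) -> str:
    """Markdown rendering of the stratification/RR/discrimination tables."""
    lines: list[str] = ["# Study report", ""]
    lines.append("## LOS by risk category (testing cohort)")
    lines.append("")
    lines.append("| model | category | share % | RR (95% CI) | conditional mean LOS |")
    lines.append("|---|---|---|---|---|")
    for model, tab in report["stratification"].items():
        for row in tab["rows"]:
            lo, hi = row["rr_ci"]
            lines.append(
                f"| {model} | {row['category']} | {row['share_pct']:.1f} "
                f"| {row['rr']:.2f} ({lo:.2f}, {hi:.2f}) | {row['conditional_mean_los']:.1f} |"
            )
    lines.append("")
    lines.append("## Model fit and nonnested comparison")
    lines.append("")
    for row in report["loglik"]:
        lines.append(f"- {row['model']}: LL = {row['loglik']:.2f} (n = {row['n']})")
    for name, c in report["nonnested_tests"].items():
        lines.append(
            f"- {name}: z = {c['z']:.3f}, p = {c['p']:.4f} (favors {c['favors']}); "
            f"cluster-aggregated z = {c['z_clustered']:.3f}, p = {c['p_clustered']:.4f}"
        )
    lines.append("")
    lines.append("## Extended LOS (>= 10 days) discrimination")
    lines.append("")
    for model, a in report["discrimination"]["auc"].items():
        lines.append(f"- {model}: AUC = {a['auc']:.3f} (95% CI {a['ci'][0]:.3f}, {a['ci'][1]:.3f})")
    idi_s = report["discrimination"]["idi"]
    lines.append(
        f"- IDI (Wu over TSPC) = {idi_s['idi_wu_over_tspc']:.4f} "
        f"(95% CI {idi_s['ci'][0]:.4f}, {idi_s['ci'][1]:.4f})"
    )
    if report.get("grown_tree"):
        lines.append("")
        lines.append("## Re-grown prognostic tree (learning cohort)")
        lines.append("")
        lines.append("```")
        lines.append(report["grown_tree"]["render"])
        lines.append("```")
        lines.append(
            f"- matches published partition: {report['grown_tree']['matches_published_partition']}"
        )
    lines.append("")
    return "\n".join(lines)
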