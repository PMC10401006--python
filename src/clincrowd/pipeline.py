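"""End-to-end orchestration: configuration, file I/O, analysis, reporting.

The response schema is delimited text with header
``trial_id,vignette_id,condition,clinician_id,round,estimate,recommendation``.
External files with other column names can be imported through a
column-mapping hook.  All randomness flows from one master seed through
named substreams (trial generation, permutation tests, power simulation).
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml

from . import core, generator, inference, metrics
from .core import CONTROL, NETWORK, TrialConfig, TrialRecord
from .errors import InvalidParametersError, MissingDataError

__version__ = "0.1.0"

logger = logging.getLogger(__name__)

RESPONSE_COLUMNS = (
    "trial_id",
    "vignette_id",
    "condition",
    "clinician_id",
    "round",
    "estimate",
    "recommendation",
)


@dataclass(frozen=True)
class Vignette:
    """One clinical case: correct risk value, options, decision thresholds."""

    id: str
    truth: float
    options: tuple
    correct_option: str
    thresholds: tuple


#: Seven default vignettes spanning low to high true risk, with decision
#: bands wide enough that a realistic share of initial estimates (roughly a
#: quarter to three-quarters, varying by case) start on the correct option.
DEFAULT_OPTIONS = ("discharge", "observation_unit", "admit")
DEFAULT_VIGNETTES = (
    Vignette("v1", 8.0, DEFAULT_OPTIONS, "discharge", (25.0, 60.0)),
    Vignette("v2", 20.0, DEFAULT_OPTIONS, "observation_unit", (12.0, 35.0)),
    Vignette("v3", 30.0, DEFAULT_OPTIONS, "observation_unit", (18.0, 45.0)),
    Vignette("v4", 45.0, DEFAULT_OPTIONS, "observation_unit", (30.0, 60.0)),
    Vignette("v5", 55.0, DEFAULT_OPTIONS, "observation_unit", (40.0, 70.0)),
    Vignette("v6", 70.0, DEFAULT_OPTIONS, "admit", (40.0, 62.0)),
    Vignette("v7", 85.0, DEFAULT_OPTIONS, "admit", (35.0, 70.0)),
)


@dataclass
class StudyConfig:
    """Full study specification: vignettes, shape, generator, analysis options."""

    vignettes: tuple = DEFAULT_VIGNETTES
    n_network: int = 8
    n_control: int = 4
    n_clinicians: int = 40
    n_rounds: int = 3
    degree: int = 4
    generator: generator.GeneratorConfig = field(
        default_factory=generator.GeneratorConfig
    )
    master_seed: int = 0
    binning: str = "pooled"
    norm: str = "fixed"
    jt_mode: str = "auto"
    n_quartiles: int = 4
    n_deciles: int = 10
    confidence: float = 0.95

    def __post_init__(self):
        ids = [v.id for v in self.vignettes]
        if len(ids) != len(set(ids)):
            raise InvalidParametersError("vignette ids must be unique")
        if self.norm not in ("fixed", "observed"):
            raise InvalidParametersError("norm must be 'fixed' or 'observed'")

    def vignette(self, vid: str) -> Vignette:
        for v in self.vignettes:
            if v.id == vid:
                return v
        raise InvalidParametersError(f"unknown vignette {vid!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["vignettes"] = [dataclasses.asdict(v) for v in self.vignettes]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "vignettes" in d:
            d["vignettes"] = tuple(
                Vignette(
                    id=v["id"],
                    truth=float(v["truth"]),
                    options=tuple(v["options"]),
                    correct_option=v["correct_option"],
                    thresholds=tuple(v["thresholds"]),
                )
                for v in d["vignettes"]
            )
        if "generator" in d and isinstance(d["generator"], dict):
            g = dict(d["generator"])
            if "thresholds" in g:
                g["thresholds"] = tuple(g["thresholds"])
            d["generator"] = generator.GeneratorConfig(**g)
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> StudyConfig:
    with open(path) as fh:
        return StudyConfig.from_dict(yaml.safe_load(fh))


def save_config(config: StudyConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True, default_flow_style=False)


# ---------------------------------------------------------------------------
# Response I/O


def responses_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = []
    for t in trials:
        for r in t.responses:
            rows.append(
                (
                    t.trial_id,
                    t.config.vignette_id,
                    t.config.condition,
                    r.clinician_id,
                    r.round,
                    r.estimate,
                    r.recommendation,
                )
            )
    return pd.DataFrame(rows, columns=list(RESPONSE_COLUMNS))


def write_responses(trials: Iterable[TrialRecord], path) -> None:
    # %.17g keeps doubles bit-exact through the text round-trip
    responses_frame(trials).to_csv(path, index=False, float_format="%.17g")


@dataclass
class RowError:
    """One malformed input row: 1-based data line number and a named reason."""

    line: int
    reason: str
    detail: str


@dataclass
class ReadResult:
    trials: list
    row_errors: list
    n_rows: int


def read_responses(
    path,
    config: StudyConfig,
    edges_path=None,
    column_map: Optional[dict] = None,
) -> ReadResult:
    """Parse a response file into validated TrialRecords.

    ``column_map`` renames external columns onto the documented schema
    (importer hook).  Malformed rows are collected into ``row_errors`` with
    line numbers and skipped; missing columns raise immediately.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    missing = set(RESPONSE_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidParametersError(
            f"response file missing columns: {sorted(missing)}"
        )

    topologies = core.read_edge_list(edges_path) if edges_path else {}

    errors = []
    keep = np.ones(len(df), dtype=bool)
    known_vignettes = {v.id: v for v in config.vignettes}
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        vid = str(row.vignette_id)
        if vid not in known_vignettes:
            errors.append(RowError(line, "unknown-vignette", vid))
            keep[i] = False
            continue
        v = known_vignettes[vid]
        try:
            est = float(row.estimate)
        except (TypeError, ValueError):
            errors.append(RowError(line, "non-numeric-estimate", str(row.estimate)))
            keep[i] = False
            continue
        if not 0.0 <= est <= 100.0:
            errors.append(RowError(line, "estimate-out-of-range", f"{est}"))
            keep[i] = False
            continue
        if str(row.recommendation) not in v.options:
            errors.append(
                RowError(line, "unknown-recommendation", str(row.recommendation))
            )
            keep[i] = False
            continue
        if str(row.condition) not in (NETWORK, CONTROL):
            errors.append(RowError(line, "unknown-condition", str(row.condition)))
            keep[i] = False

    df = df[keep]
    trials = []
    for tid, grp in df.groupby("trial_id", sort=False):
        vid = str(grp["vignette_id"].iloc[0])
        v = known_vignettes[vid]
        condition = str(grp["condition"].iloc[0])
        n_clin = grp["clinician_id"].nunique()
        n_rounds = int(grp["round"].max())
        cfg = TrialConfig(
            vignette_id=vid,
            condition=condition,
            truth=v.truth,
            options=tuple(v.options),
            correct_option=v.correct_option,
            n_clinicians=n_clin,
            n_rounds=n_rounds,
        )
        responses = [
            core.ClinicianRoundResponse(
                clinician_id=str(r.clinician_id),
                round=int(r.round),
                estimate=float(r.estimate),
                recommendation=str(r.recommendation),
            )
            for r in grp.itertuples(index=False)
        ]
        trials.append(
            TrialRecord(
                trial_id=str(tid),
                config=cfg,
                responses=responses,
                topology=topologies.get(str(tid)),
            )
        )
    if errors:
        logger.warning("read_responses: %d malformed rows skipped", len(errors))
    return ReadResult(trials=trials, row_errors=errors, n_rows=len(df))


# ---------------------------------------------------------------------------
# Pipeline stages


def run_simulate(config: StudyConfig, out_dir) -> list:
    """Simulate the configured study and write responses, edges, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials = generator.simulate_study(
        config.vignettes,
        config.generator,
        n_network=config.n_network,
        n_control=config.n_control,
        master_seed=config.master_seed,
        degree=config.degree,
        n_clinicians=config.n_clinicians,
        n_rounds=config.n_rounds,
    )
    write_responses(trials, out / "responses.csv")
    core.write_edge_list(out / "edges.csv", trials)
    manifest = {
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "n_trials": len(trials),
        "version": __version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return trials


def _tests_row(name: str, tr: inference.TestResult) -> dict:
    return {
        "name": name,
        "method": tr.method,
        "statistic": tr.statistic,
        "p_value": tr.p_value,
        "sidedness": tr.sidedness,
        "mode": tr.mode,
        "n": "/".join(str(x) for x in tr.n),
    }


def run_analyze(trials: Iterable[TrialRecord], config: StudyConfig) -> dict:
    """Execute the full analysis chain on a validated dataset.

    Returns a bundle of DataFrames: trial summaries, overall condition
    contrasts, the condition x quartile summary table, quartile-level
    differential contrasts, the decile revision-magnitude table, the
    recommendation-switch table, and a flat table of every test performed.
    """
    trials = list(trials)
    violations = [v for t in trials for v in core.validate_trial(t)]
    if violations:
        raise MissingDataError(
            f"{len(violations)} validation violations; first: "
            f"{violations[0].rule}: {violations[0].detail}"
        )

    final = config.n_rounds
    panel_raw = metrics.build_panel(trials)
    if config.norm == "fixed":
        bounds = metrics.DEFAULT_BOUNDS
    else:
        bounds = metrics.observed_bounds(panel_raw["error"])
    panel = metrics.build_panel(trials, bounds)
    clin = metrics.clinician_table(
        panel, config.n_quartiles, config.n_deciles, binning=config.binning
    )
    tsum = metrics.trial_summaries(trials, bounds)
    tests = []

    # --- overall condition-level accuracy, trial-level units
    net = tsum[tsum["condition"] == NETWORK]
    ctl = tsum[tsum["condition"] == CONTROL]
    overall_rows = []
    for cond, sub in ((NETWORK, net), (CONTROL, ctl)):
        if sub.empty:
            continue
        overall_rows.append(
            {
                "condition": cond,
                "n_trials": len(sub),
                "baseline_accuracy_pct": 100.0 * sub["mean_accuracy_r1"].mean(),
                "final_accuracy_pct": 100.0 * sub[f"mean_accuracy_r{final}"].mean(),
                "accuracy_improvement_pp": sub[f"acc_change_1{final}"].mean(),
                "baseline_correct_rate": sub["correct_rate_r1"].mean(),
                "final_correct_rate": sub[f"correct_rate_r{final}"].mean(),
                "correct_rate_change": sub[f"rate_change_1{final}"].mean(),
            }
        )
    overall = pd.DataFrame(overall_rows)

    if not net.empty and not ctl.empty:
        tests.append(
            _tests_row(
                "baseline_accuracy_network_vs_control",
                inference.wilcoxon_rank_sum(
                    net["mean_accuracy_r1"], ctl["mean_accuracy_r1"]
                ),
            )
        )
        tests.append(
            _tests_row(
                "accuracy_improvement_network_vs_control",
                inference.wilcoxon_rank_sum(
                    net[f"acc_change_1{final}"], ctl[f"acc_change_1{final}"]
                ),
            )
        )
        tests.append(
            _tests_row(
                "rate_change_network_vs_control",
                inference.wilcoxon_rank_sum(
                    net[f"rate_change_1{final}"], ctl[f"rate_change_1{final}"]
                ),
            )
        )
    for cond, sub in ((NETWORK, net), (CONTROL, ctl)):
        if sub.empty:
            continue
        diffs = sub[f"acc_change_1{final}"].to_numpy()
        if np.any(diffs != 0):
            tests.append(
                _tests_row(
                    f"accuracy_improvement_within_{cond}",
                    inference.wilcoxon_signed_rank(diffs),
                )
            )
        rdiffs = sub[f"rate_change_1{final}"].to_numpy()
        if np.any(rdiffs != 0):
            tests.append(
                _tests_row(
                    f"rate_change_within_{cond}",
                    inference.wilcoxon_signed_rank(rdiffs),
                )
            )

    # --- condition x quartile summary table
    quartile_summary = metrics.tabulate_quartile_summary(
        trials, binning=config.binning, bounds=bounds
    )

    # --- quartile differential contrasts (clinician- and trial-level modes)
    chg_col = f"acc_change_1{final}"
    q_rows = []
    for q in range(1, config.n_quartiles + 1):
        sub = clin[clin["quartile"] == q]
        a = sub.loc[sub["condition"] == CONTROL, chg_col].to_numpy()
        b = sub.loc[sub["condition"] == NETWORK, chg_col].to_numpy()
        row = {
            "quartile": q,
            "n_network": b.size,
            "n_control": a.size,
            "mean_change_network_pp": b.mean() if b.size else np.nan,
            "mean_change_control_pp": a.mean() if a.size else np.nan,
        }
        row["difference_pp"] = row["mean_change_network_pp"] - row[
            "mean_change_control_pp"
        ]
        if a.size and b.size:
            tr = inference.wilcoxon_rank_sum(b, a)
            ci = inference.rank_sum_ci(a, b, confidence=config.confidence)
            row["ranksum_p"] = tr.p_value
            row["shift_estimate_pp"] = ci.estimate
            row["shift_ci_low_pp"] = ci.lower
            row["shift_ci_high_pp"] = ci.upper
            tests.append(_tests_row(f"quartile_{q}_change_network_vs_control", tr))
            # trial-level variant: per-trial mean change within the quartile
            tl = (
                clin[clin["quartile"] == q]
                .groupby(["condition", "trial_id"])[chg_col]
                .mean()
            )
            conds = tl.index.get_level_values(0)
            a_t = tl[conds == CONTROL].to_numpy()
            b_t = tl[conds == NETWORK].to_numpy()
            if a_t.size and b_t.size:
                tr_t = inference.wilcoxon_rank_sum(b_t, a_t)
                row["ranksum_p_trial_level"] = tr_t.p_value
                tests.append(
                    _tests_row(
                        f"quartile_{q}_change_network_vs_control_trial_level", tr_t
                    )
                )
        q_rows.append(row)
    quartile_contrasts = pd.DataFrame(q_rows)

    # --- decile revision-magnitude trend in the network condition
    netclin = clin[clin["condition"] == NETWORK]
    decile_rows = []
    groups = []
    for dec in range(1, config.n_deciles + 1):
        vals = netclin.loc[netclin["decile"] == dec, "revision_magnitude"].to_numpy()
        groups.append(vals)
        decile_rows.append(
            {
                "decile": dec,
                "n": vals.size,
                "mean_revision_magnitude_pp": vals.mean() if vals.size else np.nan,
            }
        )
    decile_revision = pd.DataFrame(decile_rows)
    revision_coefficient = np.nan
    if all(g.size for g in groups):
        jt = inference.jonckheere_terpstra(
            groups,
            sidedness=inference.TWO_SIDED,
            mode=config.jt_mode,
            seed=_substream(config.master_seed, "permutation"),
        )
        tests.append(_tests_row("revision_magnitude_decile_trend", jt))
        # positive revision coefficient <=> revision magnitude falls with
        # initial accuracy; report the rank correlation of error vs revision
        err1 = 100.0 * (1.0 - netclin["acc_r1"])
        if netclin["revision_magnitude"].nunique() > 1 and err1.nunique() > 1:
            sp = inference.spearman(err1, netclin["revision_magnitude"])
            revision_coefficient = sp.statistic
            tests.append(_tests_row("revision_coefficient_error_vs_revision", sp))

    # --- recommendation switching among initially-incorrect clinicians
    sw_rows = []
    init_wrong = clin[~clin["correct_r1"]]
    for q in range(1, config.n_quartiles + 1):
        sub = init_wrong[init_wrong["quartile"] == q]
        b = sub.loc[sub["condition"] == NETWORK, f"correct_r{final}"].astype(float)
        a = sub.loc[sub["condition"] == CONTROL, f"correct_r{final}"].astype(float)
        row = {
            "quartile": q,
            "n_network_initially_incorrect": int(b.size),
            "n_control_initially_incorrect": int(a.size),
            "switch_rate_network": b.mean() if b.size else np.nan,
            "switch_rate_control": a.mean() if a.size else np.nan,
        }
        row["difference"] = row["switch_rate_network"] - row["switch_rate_control"]
        if a.size >= 2 and b.size >= 2:
            try:
                tt = inference.two_sample_t(b, a, pooled=True)
                row["t_p"] = tt.p_value
                tests.append(_tests_row(f"quartile_{q}_switch_network_vs_control", tt))
            except inference.DegenerateInputError:
                row["t_p"] = np.nan
        sw_rows.append(row)
    switch_summary = pd.DataFrame(sw_rows)
    if len(init_wrong) >= 3 and init_wrong[chg_col].nunique() > 1:
        sp_sw = inference.spearman(
            init_wrong[chg_col], init_wrong[f"correct_r{final}"].astype(float)
        )
        tests.append(_tests_row("accuracy_change_vs_switch_to_correct", sp_sw))

    tests_df = pd.DataFrame(tests)
    meta = pd.DataFrame(
        [
            {
                "config_hash": config.config_hash(),
                "master_seed": config.master_seed,
                "norm": config.norm,
                "binning": config.binning,
                "n_trials": len(trials),
                "n_clinicians_excluded": clin.attrs.get("n_excluded", 0),
                "revision_coefficient": revision_coefficient,
                "version": __version__,
            }
        ]
    )
    return {
        "meta": meta,
        "overall": overall,
        "trial_summaries": tsum,
        "quartile_summary": quartile_summary,
        "quartile_contrasts": quartile_contrasts,
        "decile_revision": decile_revision,
        "switch_summary": switch_summary,
        "tests": tests_df,
    }


BUNDLE_TABLES = (
    "meta",
    "overall",
    "trial_summaries",
    "quartile_summary",
    "quartile_contrasts",
    "decile_revision",
    "switch_summary",
    "tests",
)


def _substream(master_seed: int, name: str) -> int:
    """Named integer substream of the master seed (stays below 2**31)."""
    key = {"generation": 0, "permutation": 1, "power": 2}[name]
    return int(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(100 + key,)).generate_state(1)[0]
        % (2**31)
    )


def save_bundle(bundle: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in BUNDLE_TABLES:
        if name in bundle:
            bundle[name].to_csv(out / f"{name}.csv", index=False, float_format="%.10g")


def load_bundle(results_dir) -> dict:
    out = Path(results_dir)
    bundle = {}
    for name in BUNDLE_TABLES:
        path = out / f"{name}.csv"
        if path.exists():
            bundle[name] = pd.read_csv(path)
    return bundle


def run_report(bundle: dict) -> str:
    """Render a bundle as a human-readable plain-text report."""
    required = [
        "meta",
        "overall",
        "quartile_summary",
        "quartile_contrasts",
        "decile_revision",
        "switch_summary",
        "tests",
    ]
    for name in required:
        if name not in bundle:
            raise MissingDataError(f"results bundle missing stage: {name}")

    def fmt(df: pd.DataFrame) -> str:
        return df.to_string(
            index=False, float_format=lambda x: f"{x:.4f}", na_rep="NA"
        )

    meta = bundle["meta"].iloc[0]
    buf = io.StringIO()
    w = buf.write
    w("clincrowd analysis report\n")
    w(f"config_hash={meta['config_hash']} master_seed={meta['master_seed']}\n")
    w(
        f"norm={meta['norm']} binning={meta['binning']} "
        f"n_trials={meta['n_trials']} excluded={meta['n_clinicians_excluded']}\n\n"
    )
    w("== Overall accuracy and recommendations (trial-level means) ==\n")
    w(fmt(bundle["overall"]) + "\n\n")
    w("== Condition x initial-accuracy quartile summary (1 = least accurate) ==\n")
    w(fmt(bundle["quartile_summary"]) + "\n\n")
    w("== Quartile differential contrasts, network - control ==\n")
    w(fmt(bundle["quartile_contrasts"]) + "\n\n")
    w("== Revision magnitude by initial-accuracy decile (network arm) ==\n")
    w(fmt(bundle["decile_revision"]) + "\n\n")
    w("== Recommendation switches among initially incorrect clinicians ==\n")
    w(fmt(bundle["switch_summary"]) + "\n\n")
    w("== Statistical tests ==\n")
    w(fmt(bundle["tests"]) + "\n")
    return buf.getvalue()
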