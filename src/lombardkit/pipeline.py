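"""End-to-end orchestration: config -> attempts -> features -> inference -> report.

A run consumes either a synthetic-generator configuration or a directory of
per-participant files (annotation tiers, body/face tracks, acoustic
contours), segments first communicative attempts, extracts the nine
features, and walks the inference ladder per feature, writing a report as
TSV + JSON + markdown with a full decision trace. Runs are deterministic
given the seed; no timestamps enter any written artifact.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import eaf as _eaf
from . import io as _io
from .annotations import build_rounds, first_attempts, modality_table
from .extract import ExtractionConfig, FEATURE_COLUMNS, feature_table
from .glmm import CUMLOGIT, GAMMA_LOG, GAUSSIAN, POISSON, FitResult
from .inference import (
    ContrastSet,
    InteractionResult,
    LadderResult,
    LRTResult,
    SensitivityResult,
    VIFReport,
    choose_family,
    interaction_analysis,
    modality_frequency_analysis,
    noise_effect_analysis,
    outlier_sensitivity,
    vif_screen,
)
from .synthetic import CONDITIONS, GeneratorConfig, generate_dataset
from .types import GESTURE_ONLY, MULTIMODAL, SPEECH_ONLY

log = logging.getLogger("lombardkit.pipeline")

SPEECH_FEATURES = (
    "max_intensity_db", "max_f0_hz", "max_mouth_opening_mm",
    "mean_lip_movement_mm_s", "peak_lip_velocity_mm_s",
)
GESTURE_FEATURES = (
    "peak_velocity_m_s", "max_distance_m", "vertical_amplitude",
    "holdtime_s", "submovements",
)

#: response families per feature; counts and durations get a data-driven
#: comparison against gaussian, the ordinal feature is always cumulative-logit
FAMILY_CANDIDATES: dict[str, tuple[str, ...]] = {
    "submovements": (POISSON, GAUSSIAN),
    "holdtime_s": (GAMMA_LOG, GAUSSIAN),
    "vertical_amplitude": (CUMLOGIT,),
}


@dataclass
class PipelineConfig:
    """Everything a run needs; YAML-serializable."""

    generator: GeneratorConfig | None = None
    data_dir: str | None = None
    use_latent_features: bool = False  # synthetic only: skip track rendering
    gap_ms: float = 200.0
    condition_levels: list[str] = field(default_factory=lambda: list(CONDITIONS))
    features: list[str] = field(default_factory=lambda: list(FEATURE_COLUMNS))
    alpha: float = 0.05
    run_interaction: bool = True
    run_modality_frequency: bool = True
    run_sensitivity: bool = True
    make_figures: bool = False
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        gen = payload.pop("generator", None)
        cfg = cls(**payload)
        if gen is not None:
            cfg.generator = GeneratorConfig(**gen)
        return cfg

    def validate(self) -> None:
        if self.generator is None and self.data_dir is None:
            raise ValueError("config needs either a generator block or a data_dir")
        if self.data_dir is not None and not Path(self.data_dir).exists():
            raise ValueError(f"data_dir {self.data_dir} does not exist")
        if self.gap_ms <= 0:
            raise ValueError("gap_ms must be positive")


@dataclass
class AnalysisReport:
    modality_table: pd.DataFrame
    feature_table: pd.DataFrame
    vif: VIFReport | None
    families: dict[str, str]
    family_records: dict[str, pd.DataFrame]
    ladders: dict[str, LadderResult]
    interactions: dict[str, InteractionResult]
    modality_frequency: FitResult | None
    sensitivity: dict[str, SensitivityResult]
    trace: list[dict]
    accounting: dict

    def model_comparison_table(self) -> pd.DataFrame:
        rows = []
        for feat, lad in self.ladders.items():
            rows.append(
                {
                    "feature": feat, "family": lad.family,
                    "chisq": lad.lrt.chisq, "df": lad.lrt.df, "p": lad.lrt.p,
                    "chisq_vs_intercept_null": lad.lrt_vs_intercept_null.chisq,
                    "df_vs_intercept_null": lad.lrt_vs_intercept_null.df,
                    "random_slopes": ",".join(
                        rt.name for rt in lad.full_fit.random_terms if rt.slope
                    ),
                }
            )
        return pd.DataFrame(rows)

    def contrast_table(self) -> pd.DataFrame:
        rows = []
        for feat, lad in self.ladders.items():
            if lad.contrasts is None:
                continue
            t = lad.contrasts.rows.copy()
            t.insert(0, "feature", feat)
            t.insert(1, "scale", lad.contrasts.scale)
            rows.append(t)
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()

    def to_json_dict(self) -> dict:
        return {
            "accounting": self.accounting,
            "modality_table": json.loads(self.modality_table.to_json(orient="index")),
            "vif": None if self.vif is None else {
                "vif": {k: _num(v) for k, v in self.vif.vif.items()},
                "excluded": self.vif.excluded, "n_complete": self.vif.n_complete,
            },
            "families": self.families,
            "models": {f: _ladder_dict(l) for f, l in self.ladders.items()},
            "interactions": {f: _interaction_dict(i) for f, i in self.interactions.items()},
            "modality_frequency": None if self.modality_frequency is None
            else _fit_dict(self.modality_frequency),
            "sensitivity": {f: _sensitivity_dict(s) for f, s in self.sensitivity.items()},
            "trace": self.trace,
        }

    def content_hash(self) -> str:
        payload = json.dumps(self.to_json_dict(), sort_keys=True, default=_num)
        return hashlib.sha256(payload.encode()).hexdigest()

    def write(self, out_dir: str | Path) -> dict:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["feature_table"] = out / "feature_table.tsv"
        self.feature_table.to_csv(paths["feature_table"], sep="\t", index=False)
        paths["modality_table"] = out / "modality_table.tsv"
        self.modality_table.to_csv(paths["modality_table"], sep="\t")
        paths["model_comparison"] = out / "model_comparison.tsv"
        self.model_comparison_table().to_csv(paths["model_comparison"], sep="\t", index=False)
        paths["contrasts"] = out / "contrasts.tsv"
        self.contrast_table().to_csv(paths["contrasts"], sep="\t", index=False)
        paths["report_json"] = out / "report.json"
        paths["report_json"].write_text(
            json.dumps(self.to_json_dict(), indent=2, sort_keys=True, default=_num)
        )
        paths["report_md"] = out / "report.md"
        paths["report_md"].write_text(self.to_markdown())
        return paths

    def to_markdown(self) -> str:
        lines = ["# Noise-adaptation analysis report", ""]
        acc = self.accounting
        lines += [
            f"Rounds in: {acc['rounds_in']}; first attempts analyzed: "
            f"{acc['attempts_analyzed']}; rounds dropped: {acc['rounds_dropped']}.",
            "",
            "## Modality usage (counts, row % per noise level)",
            "",
            self.modality_table.to_markdown(),
            "",
            "## Condition effects (likelihood-ratio tests vs structure-matched null)",
            "",
        ]
        mc = self.model_comparison_table()
        if len(mc):
            lines += [mc.round(4).to_markdown(index=False), ""]
        ct = self.contrast_table()
        if len(ct):
            lines += ["## Pairwise condition contrasts (Tukey-adjusted)", "",
                      ct.round(4).to_markdown(index=False), ""]
        if self.interactions:
            lines.append("## Noise x modality interactions")
            lines.append("")
            for f, ia in self.interactions.items():
                lines.append(
                    f"- {f}: chisq({ia.lrt.df}) = {ia.lrt.chisq:.2f}, p = {ia.lrt.p:.4f}"
                )
            lines.append("")
        if self.sensitivity:
            lines.append("## Outlier sensitivity (mean + 3 SD rule)")
            lines.append("")
            for f, s in self.sensitivity.items():
                lines.append(
                    f"- {f}: removed {s.n_removed}; significance pattern "
                    f"{'agrees' if s.pattern_agrees else 'DIFFERS'}"
                )
            lines.append("")
        return "\n".join(lines)


def _num(x):
    if isinstance(x, (np.floating, np.integer)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, float) and (math_isnan(x)):
        return None
    return x


def math_isnan(x) -> bool:
    try:
        return bool(np.isnan(x))
    except TypeError:
        return False


def _fit_dict(fit: FitResult) -> dict:
    return {
        "formula": fit.formula, "family": fit.family,
        "coefficients": {
            n: {"estimate": float(e), "se": float(s)}
            for n, e, s in zip(fit.param_names, fit.params, fit.se)
        },
        "vc_sd": {k: float(v) for k, v in fit.vc.items()},
        "scale": fit.scale, "shape": fit.shape,
        "loglik": float(fit.loglik), "n": fit.n, "n_params": fit.n_params,
        "converged": fit.converged, "singular": fit.singular,
        "singular_terms": fit.singular_terms,
    }


def _lrt_dict(l: LRTResult) -> dict:
    return {"chisq": float(l.chisq), "df": int(l.df), "p": float(l.p),
            "null": l.formula_null, "full": l.formula_full}


def _contrasts_dict(c: ContrastSet | None):
    if c is None:
        return None
    return {"scale": c.scale, "rows": c.rows.to_dict(orient="records")}


def _ladder_dict(l: LadderResult) -> dict:
    return {
        "family": l.family, "lrt": _lrt_dict(l.lrt),
        "lrt_vs_intercept_null": _lrt_dict(l.lrt_vs_intercept_null),
        "full_fit": _fit_dict(l.full_fit), "contrasts": _contrasts_dict(l.contrasts),
        "trace": l.trace,
    }


def _interaction_dict(i: InteractionResult) -> dict:
    return {
        "family": i.family, "lrt": _lrt_dict(i.lrt),
        "lrt_interaction_only": _lrt_dict(i.lrt_interaction_only),
        "full_fit": _fit_dict(i.full_fit),
        "simple_effects": {k: _contrasts_dict(v) for k, v in i.simple_effects.items()},
    }


def _sensitivity_dict(s: SensitivityResult) -> dict:
    return {
        "n_removed": s.n_removed, "lrt_all": _lrt_dict(s.lrt_all),
        "lrt_trimmed": _lrt_dict(s.lrt_trimmed), "pattern_agrees": s.pattern_agrees,
    }


# ---------------------------------------------------------------------------
# input assembly


def _collect_feature_table(config: PipelineConfig) -> tuple[pd.DataFrame, dict, list[dict]]:
    trace: list[dict] = []
    rounds_in = 0
    dropped = 0
    parts: list[pd.DataFrame] = []
    modality_rows: list[pd.DataFrame] = []

    if config.generator is not None:
        gen = dataclasses.replace(config.generator, seed=config.seed)
        sessions, truth = generate_dataset(gen, render_tracks=not config.use_latent_features)
        trace.append({"step": "input", "source": "synthetic",
                      "n_participants": gen.n_participants, "n_items": gen.n_items,
                      "latent_features": config.use_latent_features})
        if config.use_latent_features:
            tab = truth.rename(columns={})[
                ["participant", "item", "condition", "modality"] + list(FEATURE_COLUMNS)
            ].copy()
            tab.insert(0, "attempt_id",
                       tab["participant"] + ":" + tab["item"] + ":1")
            tab["flags"] = ""
            rounds_in = len(tab)
            return tab, {"rounds_in": rounds_in, "attempts_analyzed": len(tab),
                         "rounds_dropped": 0}, trace
        per_participant = [
            (s.participant_id,
             [e for evs in s.tiers.values() for e in evs],
             s.round_meta, s.body_track, s.face_track, s.contour)
            for s in sessions
        ]
    else:
        per_participant = []
        data_dir = Path(config.data_dir)
        for rounds_path in sorted(data_dir.glob("*_rounds.csv")):
            pid = rounds_path.name[: -len("_rounds.csv")]
            meta = _io.read_round_csv(rounds_path)
            tiers_eaf = data_dir / f"{pid}.eaf"
            tiers_csv = data_dir / f"{pid}_tiers.csv"
            if tiers_eaf.exists():
                events = [e for evs in _eaf.read_eaf(tiers_eaf).values() for e in evs]
            elif tiers_csv.exists():
                events = _io.read_tier_csv(tiers_csv)
            else:
                raise FileNotFoundError(f"no tier file for participant {pid}")
            events.sort(key=lambda e: (e.onset_ms, e.offset_ms))

            def _opt(path, reader, kind):
                if path.exists():
                    return reader(path)
                trace.append({"step": "input", "participant": pid,
                              "missing": kind, "effect": f"{kind} features skipped"})
                return None

            body = _opt(data_dir / f"{pid}_body.csv", _io.read_body_track, "body")
            face = _opt(data_dir / f"{pid}_face.csv", _io.read_face_track, "face")
            contour = _opt(data_dir / f"{pid}_contour.csv", _io.read_contour_csv, "audio")
            per_participant.append((pid, events, meta, body, face, contour))
        trace.append({"step": "input", "source": str(data_dir),
                      "n_participants": len(per_participant)})

    ext = ExtractionConfig()
    for pid, events, meta, body, face, contour in per_participant:
        rounds = build_rounds(events, meta, config.gap_ms)
        rounds_in += len(rounds)
        firsts = first_attempts(rounds)
        dropped += len(rounds) - len(firsts)
        for r in rounds:
            if not r.attempts:
                trace.append({"step": "segmentation", "participant": pid,
                              "item": r.item, "dropped": "round without attempts"})
        parts.append(feature_table(firsts, body, face, contour, ext))
    tab = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
    accounting = {"rounds_in": rounds_in, "attempts_analyzed": len(tab),
                  "rounds_dropped": dropped}
    return tab, accounting, trace


def make_modality_report(
    attempts_or_table, conditions: list[str] | None = None
) -> pd.DataFrame:
    """Counts + one-decimal row percentages per condition, with a totals row."""
    if isinstance(attempts_or_table, pd.DataFrame):
        tab = attempts_or_table
        if "condition" not in tab.columns:
            tab = tab.reindex(columns=["condition", "modality"])
        conditions = conditions or list(pd.unique(tab["condition"].dropna()))
        counts = pd.DataFrame(0, index=conditions,
                              columns=[SPEECH_ONLY, GESTURE_ONLY, MULTIMODAL], dtype=int)
        for c in conditions:
            sub = tab[tab["condition"] == c]
            for m in counts.columns:
                counts.loc[c, m] = int((sub["modality"] == m).sum())
        out = counts.copy()
        out["total"] = counts.sum(axis=1)
        for m in counts.columns:
            denom = out["total"].replace(0, np.nan)
            out[f"{m}_pct"] = (100.0 * counts[m] / denom).round(1).fillna(0.0)
    else:
        out = modality_table(attempts_or_table, conditions)
    totals = out[[SPEECH_ONLY, GESTURE_ONLY, MULTIMODAL, "total"]].sum(axis=0)
    out.loc["total", [SPEECH_ONLY, GESTURE_ONLY, MULTIMODAL, "total"]] = totals
    return out


# ---------------------------------------------------------------------------
# the run


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute the full analysis; raises with the stage name on any failure."""
    config.validate()
    stage = "input"
    try:
        tab, accounting, trace = _collect_feature_table(config)
        cl = config.condition_levels

        stage = "modality_table"
        mod_table = make_modality_report(tab, cl)

        stage = "vif_screen"
        features = [f for f in config.features if f in tab.columns]
        vif = None
        kept = list(features)
        n_complete = int(tab[features].dropna().shape[0]) if features else 0
        if n_complete < 5 * (len(features) + 1):
            # too few complete cases for a stable R^2 per feature
            trace.append({"step": "vif_screen", "skipped":
                          f"only {n_complete} complete cases for {len(features)} features"})
        else:
            try:
                vif = vif_screen(tab, features)
                kept = [f for f in features if f not in vif.excluded]
                for f in vif.excluded:
                    trace.append({"step": "vif_screen", "excluded": f,
                                  "vif": vif.vif[f]})
            except ValueError as exc:
                trace.append({"step": "vif_screen", "skipped": str(exc)})

        stage = "family_choice"
        for f in list(kept):
            if f in tab.columns and tab[f].notna().sum() == 0:
                kept.remove(f)
                trace.append({"step": "feature_availability", "feature": f,
                              "skipped": "no non-missing values (input absent)"})
        # holdtime of exactly zero is left-censored at the frame resolution;
        # shift to half a frame so duration families stay applicable
        if "holdtime_s" in tab.columns:
            n_zero = int((tab["holdtime_s"] == 0).sum())
            if n_zero:
                eps = 1.0 / 60.0
                tab.loc[tab["holdtime_s"] == 0, "holdtime_s"] = eps
                trace.append({"step": "holdtime_floor", "n_zero": n_zero,
                              "floor_s": eps})
        families: dict[str, str] = {}
        family_records: dict[str, pd.DataFrame] = {}
        for f in kept:
            cands = FAMILY_CANDIDATES.get(f, (GAUSSIAN,))
            if len(cands) == 1:
                families[f] = cands[0]
            else:
                fam, rec = choose_family(tab, f, cands, condition_levels=cl)
                families[f] = fam
                family_records[f] = rec
                trace.append({"step": "family_choice", "feature": f, "chosen": fam,
                              "aic": {r["family"]: r["aic"] for r in
                                      rec.to_dict(orient="records")}})

        stage = "noise_effects"
        ladders: dict[str, LadderResult] = {}
        for f in kept:
            lad = noise_effect_analysis(tab, f, families[f], cl, config.alpha)
            ladders[f] = lad
            trace.extend({"feature": f, **t} for t in lad.trace)

        stage = "interactions"
        interactions: dict[str, InteractionResult] = {}
        if config.run_interaction:
            for f, lad in ladders.items():
                if lad.lrt.p >= config.alpha or lad.family == CUMLOGIT:
                    continue
                unimodal = SPEECH_ONLY if f in SPEECH_FEATURES else GESTURE_ONLY
                try:
                    interactions[f] = interaction_analysis(
                        tab, f, lad.family, unimodal, cl
                    )
                    trace.append({"step": "interaction", "feature": f,
                                  "chisq": interactions[f].lrt.chisq,
                                  "df": interactions[f].lrt.df,
                                  "p": interactions[f].lrt.p,
                                  "interaction_only_chisq":
                                      interactions[f].lrt_interaction_only.chisq,
                                  "interaction_only_p":
                                      interactions[f].lrt_interaction_only.p})
                except ValueError as exc:
                    trace.append({"step": "interaction", "feature": f,
                                  "skipped": str(exc)})

        stage = "modality_frequency"
        mf = modality_frequency_analysis(tab, cl) if config.run_modality_frequency else None

        stage = "sensitivity"
        sensitivity: dict[str, SensitivityResult] = {}
        if config.run_sensitivity:
            for f, lad in ladders.items():
                if lad.family == CUMLOGIT:
                    continue
                s = outlier_sensitivity(tab, f, lad.family,
                                        lad.full_fit.random_terms, cl, config.alpha)
                sensitivity[f] = s
                trace.append({"step": "sensitivity", "feature": f,
                              "n_removed": s.n_removed,
                              "pattern_agrees": s.pattern_agrees})
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report = AnalysisReport(
        modality_table=mod_table, feature_table=tab, vif=vif, families=families,
        family_records=family_records, ladders=ladders, interactions=interactions,
        modality_frequency=mf, sensitivity=sensitivity, trace=trace,
        accounting=accounting,
    )
    if config.out_dir:
        report.write(config.out_dir)
        if config.make_figures:
            from . import figures

            figures.export_report_figures(report, Path(config.out_dir) / "figures")
    return report
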