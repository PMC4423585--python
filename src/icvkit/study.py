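"""End-to-end study orchestration: simulate, measure, analyze, report.

Reproduces the two-phase protocol-evaluation dataflow on synthetic
cohorts:

* phase I — operator 1 traces every mask (the reference measurement) and
  each automated-tool simulator estimates every subject's ICV;
* phase II — operator 1 re-traces (intra-operator), operator 2 traces
  (inter-operator, reported under phase I per the measurement-table
  layout), and the tool simulators run again with fresh noise;
* the randomized subsampling reliability analysis runs per group on the
  phase-I reference tracings and yields the two protocol guidelines;
* the agreement battery (paired t, Pearson r, MRPAD) and the four-factor
  Type III GLM summarize method and operator effects.

Everything is deterministic given ``StudyConfig.master_seed``: stage seeds
are derived from it, and the report JSON is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .phantom import (
    MaskVolume,
    OperatorModel,
    PhantomSpec,
    ToolModel,
    TOOL_PRESETS,
    ac_like_spec,
    ad_like_spec,
    generate_cohort,
    simulate_operator_tracing,
    simulate_tool_icv,
)
from .reliability import (
    guideline_max_period,
    run_randomized_reliability,
    summarize_curve,
)
from .compare import (
    comparison_battery,
    comparisons_to_frame,
    factorial_glm_anova,
    intra_method_battery,
    validate_icv_table,
)

__all__ = ["StudyConfig", "run_study", "make_fixtures"]

#: Demographics per group: (age mean, age SD, female fraction), matching
#: the cohort the presets emulate (AD: 81 +/- 9.31 y, 6F/5M; AC: 71 +/-
#: 6.21 y, 9F/2M).
DEFAULT_DEMOGRAPHICS = {
    "AD": (81.0, 9.31, 6 / 11),
    "AC": (71.0, 6.21, 9 / 11),
}


@dataclass
class StudyConfig:
    """Configuration of one full simulated study."""

    master_seed: int
    out_dir: str = "study_out"
    n_subjects: int = 11
    grid_shape: tuple[int, int, int] = (192, 192, 192)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.5)
    slice_axis: int = 2
    groups: dict[str, PhantomSpec] = field(default_factory=dict)
    demographics: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DEMOGRAPHICS)
    )
    op1_jitter_sd: float = 0.35
    op2_jitter_sd: float = 0.35
    tools: dict[str, ToolModel] = field(default_factory=lambda: dict(TOOL_PRESETS))
    periods: tuple[int, ...] = tuple(range(2, 41))
    n_reps: int = 5000
    icc_threshold: float = 0.99
    confidence: float = 0.95
    spread_max: float = 0.005
    write_masks: bool = True

    def __post_init__(self) -> None:
        if not self.groups:
            self.groups = {
                "AD": ad_like_spec(self.grid_shape, self.spacing),
                "AC": ac_like_spec(self.grid_shape, self.spacing),
            }
        else:
            self.groups = {
                g: dataclasses.replace(
                    s, grid_shape=self.grid_shape, spacing=self.spacing,
                    slice_axis=self.slice_axis,
                )
                for g, s in self.groups.items()
            }
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0 < self.icc_threshold <= 1 or not 0 < self.confidence < 1:
            raise ValueError("icc_threshold/confidence out of range")
        if self.spread_max < 0 or self.n_reps < 1:
            raise ValueError("spread_max must be >= 0 and n_reps >= 1")
        for spec in self.groups.values():
            spec.validate()

    @property
    def slice_spacing(self) -> float:
        return self.spacing[self.slice_axis]

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["groups"] = {
            g: {
                "semi_axes": list(s.semi_axes),
                "roughness_amplitude": s.roughness_amplitude,
                "roughness_order": s.roughness_order,
                "target_icv_mean": s.target_icv_mean,
                "target_icv_sd": s.target_icv_sd,
            }
            for g, s in self.groups.items()
        }
        d["tools"] = {
            name: {"mult_bias": t.mult_bias, "noise_cv": t.noise_cv}
            for name, t in self.tools.items()
        }
        d["demographics"] = {g: list(v) for g, v in self.demographics.items()}
        for key in ("grid_shape", "spacing", "periods"):
            d[key] = list(d[key])
        return d

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "StudyConfig":
        d = dict(d)
        grid_shape = tuple(d.get("grid_shape", (192, 192, 192)))
        spacing = tuple(d.get("spacing", (1.0, 1.0, 1.5)))
        slice_axis = int(d.get("slice_axis", 2))
        if "groups" in d and d["groups"]:
            d["groups"] = {
                g: PhantomSpec(
                    semi_axes=tuple(s["semi_axes"]),
                    roughness_amplitude=float(s.get("roughness_amplitude", 0.0)),
                    roughness_order=int(s.get("roughness_order", 0)),
                    grid_shape=grid_shape,
                    spacing=spacing,
                    target_icv_mean=float(s.get("target_icv_mean", 1.46)),
                    target_icv_sd=float(s.get("target_icv_sd", 0.14)),
                    slice_axis=slice_axis,
                )
                for g, s in d["groups"].items()
            }
        if "tools" in d and d["tools"]:
            d["tools"] = {
                name: ToolModel(name, float(t["mult_bias"]), float(t["noise_cv"]))
                for name, t in d["tools"].items()
            }
        if "demographics" in d:
            d["demographics"] = {g: tuple(v) for g, v in d["demographics"].items()}
        for key in ("grid_shape", "spacing"):
            if key in d:
                d[key] = tuple(d[key])
        if "periods" in d:
            d["periods"] = tuple(int(m) for m in d["periods"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("write_masks", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_seed(master_seed: int, label: str) -> int:
    """Stable per-stage seed below 2^31, derived from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") & 0x7FFFFFFF


def _guideline_pair(curve, cfg: StudyConfig) -> dict[str, dict]:
    out = {}
    for criterion in ("confidence_icc", "tight_spread"):
        res = guideline_max_period(
            curve,
            criterion,
            icc_threshold=cfg.icc_threshold,
            confidence=cfg.confidence,
            spread_max=cfg.spread_max,
            slice_spacing=cfg.slice_spacing,
        )
        out[criterion] = res.to_dict()
    return out


def run_study(config: StudyConfig) -> dict[str, Any]:
    """Run the full simulated study; returns the report dict.

    All intermediate artifacts (measurement table, reliability draws and
    curves, guidelines, agreement batteries, ANOVA table, report JSON) are
    written under ``config.out_dir``; masks are written as NIfTI when
    ``config.write_masks`` is set.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config.yaml")
    seed = config.master_seed

    op1_p1 = OperatorModel(config.op1_jitter_sd, seed_offset=_stage_seed(seed, "op1p1"))
    op1_p2 = OperatorModel(config.op1_jitter_sd, seed_offset=_stage_seed(seed, "op1p2"))
    op2_p1 = OperatorModel(config.op2_jitter_sd, seed_offset=_stage_seed(seed, "op2p1"))

    icv_rows: list[dict] = []
    report: dict[str, Any] = {
        "provenance": {
            "package_version": __version__,
            "master_seed": seed,
            "config_hash": config.config_hash(),
        },
        "groups": {},
    }

    group_tracings: dict[str, list[MaskVolume]] = {}
    for group, spec in sorted(config.groups.items()):
        try:
            cohort = generate_cohort(
                spec, config.n_subjects, group, _stage_seed(seed, f"cohort:{group}")
            )
        except Exception as exc:  # surface the failing stage and input
            raise RuntimeError(f"stage 'simulate' failed for group {group}: {exc}") from exc
        demo_rng = np.random.default_rng(
            np.random.SeedSequence(_stage_seed(seed, f"demo:{group}"))
        )
        age_mean, age_sd, female_frac = config.demographics.get(group, (75.0, 8.0, 0.5))
        ages = np.round(demo_rng.normal(age_mean, age_sd, len(cohort)), 1)
        # fixed sex counts (rounded to the cohort fraction), shuffled order;
        # keeps both levels present even in tiny smoke cohorts
        n_f = int(np.clip(round(len(cohort) * female_frac), 1, len(cohort) - 1))
        sexes = np.array(["F"] * n_f + ["M"] * (len(cohort) - n_f))
        demo_rng.shuffle(sexes)

        if config.write_masks:
            from .phantom import write_cohort

            write_cohort(cohort, group, out_dir / "masks" / group,
                         sex=list(sexes), age=list(ages))

        # manual tracings
        traced: dict[tuple[str, int], list[float]] = {}
        t1_masks = []
        for i, (sid, mask, _true) in enumerate(cohort):
            m1 = simulate_operator_tracing(mask, op1_p1, i)
            t1_masks.append(m1)
            for (method, phase), tm in (
                (("manual_op1", 1), m1),
                (("manual_op1", 2), simulate_operator_tracing(mask, op1_p2, i)),
                (("manual_op2", 1), simulate_operator_tracing(mask, op2_p1, i)),
            ):
                traced.setdefault((method, phase), []).append(tm.volume_l())
        group_tracings[group] = t1_masks
        reference = traced[("manual_op1", 1)]

        # automated tools run on the underlying anatomy (true voxel volume)
        true_icvs = [t for (_s, _m, t) in cohort]
        tool_icvs: dict[tuple[str, int], np.ndarray] = {}
        for name, tool in sorted(config.tools.items()):
            for phase in (1, 2):
                tool_icvs[(name, phase)] = simulate_tool_icv(
                    true_icvs, tool, _stage_seed(seed, f"tool:{name}:{phase}:{group}")
                )

        for i, (sid, _mask, _true) in enumerate(cohort):
            base = {"subject_id": sid, "group": group, "sex": sexes[i], "age": ages[i]}
            for (method, phase), vals in traced.items():
                icv_rows.append({**base, "method": method, "phase": phase, "icv_l": vals[i]})
            for (name, phase), vals in tool_icvs.items():
                icv_rows.append({**base, "method": name, "phase": phase, "icv_l": vals[i]})

        # randomized subsampling reliability on the reference tracings
        draws = run_randomized_reliability(
            t1_masks,
            reference,
            config.periods,
            n_reps=config.n_reps,
            seed=_stage_seed(seed, f"reliability:{group}"),
        )
        curve = summarize_curve(draws)
        draws.to_csv(out_dir / f"reliability_draws_{group}.csv", index=False)
        curve.to_csv(out_dir / f"reliability_curve_{group}.csv")
        guidelines = _guideline_pair(curve, config)
        (out_dir / f"guidelines_{group}.json").write_text(
            json.dumps(guidelines, indent=2, sort_keys=True)
        )
        report["groups"][group] = {
            "true_icv_mean_l": float(np.mean(true_icvs)),
            "true_icv_sd_l": float(np.std(true_icvs, ddof=1)),
            "reliability_curve": {
                str(m): {k: float(v) for k, v in row.items()}
                for m, row in curve.iterrows()
            },
            "guidelines": guidelines,
        }

    table = pd.DataFrame(icv_rows)
    validate_icv_table(table)
    table.to_csv(out_dir / "icv_table.csv", index=False)

    # agreement batteries per group
    for group in sorted(config.groups):
        battery = comparison_battery(table, reference_method="manual_op1", group=group)
        intra = intra_method_battery(table, group=group)
        bf = comparisons_to_frame(battery)
        inf_ = comparisons_to_frame(intra)
        bf.to_csv(out_dir / f"comparisons_{group}.csv", index=False)
        inf_.to_csv(out_dir / f"intra_method_{group}.csv", index=False)
        report["groups"][group]["comparisons"] = bf.to_dict(orient="records")
        report["groups"][group]["intra_method"] = inf_.to_dict(orient="records")

    # factorial GLM on phase-I measurements, one row per subject x method
    glm_table = table[(table["phase"] == 1) & (table["method"] != "manual_op2")].copy()
    glm_table["method"] = glm_table["method"].replace({"manual_op1": "manual"})
    anova = None
    for order in (4, 3, 2, 1):
        try:
            anova = factorial_glm_anova(glm_table, max_order=order)
        except ValueError:
            continue
        break
    if anova is None:
        raise RuntimeError("stage 'compare' failed: no estimable ANOVA design")
    anova.to_csv(out_dir / "anova.csv")
    report["anova"] = {
        term: {k: float(v) for k, v in row.items()} for term, row in anova.iterrows()
    }
    report["anova_interaction_order"] = order

    report_json = json.dumps(report, indent=2, sort_keys=True, allow_nan=True)
    (out_dir / "report.json").write_text(report_json)
    return report


# ---------------------------------------------------------------------------
# Test fixtures
# ---------------------------------------------------------------------------

def make_fixtures(seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write the small deterministic fixture bundle used by the test suite.

    Includes the 10-slice constant-area profile mask (10 slices of exactly
    100 mm^2 at 1 mm spacing), an empty mask, a small rough phantom, the
    3-subject two-rater ICC worked example, and a JSON of their expected
    values.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    occ = np.zeros((12, 12, 12), dtype=np.uint8)
    occ[1:11, 1:11, 0:10] = 1
    profile_mask = MaskVolume(occ, (1.0, 1.0, 1.0), slice_axis=2)
    paths["constant_profile_mask"] = profile_mask.to_nifti(
        out_dir / "constant_profile_mask.nii.gz"
    )

    empty = MaskVolume(np.zeros((8, 8, 8), dtype=np.uint8), (1.0, 1.0, 1.0))
    paths["empty_mask"] = empty.to_nifti(out_dir / "empty_mask.nii.gz")

    spec = PhantomSpec(
        semi_axes=(16.0, 14.0, 12.0),
        roughness_amplitude=2.0,
        roughness_order=4,
        grid_shape=(48, 48, 48),
        spacing=(1.0, 1.0, 1.0),
    )
    from .phantom import generate_phantom

    small = generate_phantom(spec, _stage_seed(seed, "fixture-phantom"))
    paths["small_phantom"] = small.to_nifti(out_dir / "small_phantom.nii.gz")

    icc_df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [2.0, 3.0, 4.0]})
    paths["icc_example"] = out_dir / "icc_example.csv"
    icc_df.to_csv(paths["icc_example"], index=False)

    expected = {
        "icc_example": 2.0 / 3.0,
        "constant_profile": {
            "true_icv_l": 0.001,
            # m=3, start 0 samples slices {0,3,6,9}: 3 x 4 x 100 mm^3
            "m3_start0_icv_l": 0.0012,
        },
        "empty_icv_l": 0.0,
        "small_phantom_icv_l": small.volume_l(),
    }
    paths["expected"] = out_dir / "expected.json"
    paths["expected"].write_text(json.dumps(expected, indent=2, sort_keys=True))
    return paths
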