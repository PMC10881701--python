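"""End-to-end orchestration: cohort -> quantification -> statistics -> report.

Stages mirror the trial's analysis plan:

1. **generate** — synthetic cohort (phantoms + follow-up + labs);
2. **quantify** — segment lesion VOIs on the baseline receptor image,
   transfer them to every post-cycle emission volume, extract T/N;
3. **analyze** — paired t (primary, cycle 1, mean basis), log-ratio test,
   all-cycle two-level LMM, peak-basis variants, covariate tests,
   proportion increased;
4. **respond** — RECIST per-lobe tables at 3/6 months with Fisher's exact p;
5. **toxicity** — treatment-emergent CTCAE-style grade table.

Every artifact is a plain file (CSV/JSON); the seed and a config hash are
recorded for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import quant, response, stats
from .synthetic import CohortConfig, PatientPhantom, build_phantom, generate_cohort, \
    simulate_followup, simulate_labs, _patient_seeds, _completed_cycles
from .design import generate_randomization
from .response import DEFAULT_GRADING_RULES

__all__ = ["RunConfig", "run_pipeline", "quantify_phantom", "render_tables"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    outdir: Path = Path("intralobe_run")
    basis: str = "both"  # mean | peak | both
    stages: tuple[str, ...] = ("generate", "quantify", "analyze", "respond", "toxicity")
    write_volumes: bool = False  # also persist the NIfTI cohort

    def __post_init__(self) -> None:
        if self.basis not in ("mean", "peak", "both"):
            raise ValueError("basis must be 'mean', 'peak' or 'both'")
        object.__setattr__(self, "outdir", Path(self.outdir))

    @property
    def bases(self) -> tuple[str, ...]:
        return ("mean", "peak") if self.basis == "both" else (self.basis,)


def config_hash(config: CohortConfig) -> str:
    echo = asdict(config)
    blob = json.dumps(echo, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def quantify_phantom(phantom: PatientPhantom, n_cycles: int | None = None) -> pd.DataFrame:
    """Quantify all cycles of one phantom: segment on baseline, transfer,
    extract T/N on both bases.  Returns long rows (patient_id, cycle, basis,
    tn_ia, tn_control)."""
    segmented = []
    for lesion in phantom.lesions:
        rough = phantom.rough_voi(lesion.lesion_id)
        voi = quant.segment_lesion_voi(phantom.baseline_volume, rough)
        segmented.append((lesion.lesion_id, lesion.lobe, voi))
    rows = []
    n = len(phantom.cycle_volumes) if n_cycles is None else n_cycles
    for c in range(n):
        results, _ = quant.quantify_patient_cycle(
            phantom.patient_id, c + 1, segmented, phantom.normal_voi,
            phantom.ia_lobe, phantom.cycle_volumes[c],
            phantom.baseline_to_cycle_transforms[c],
        )
        rows.extend(dataclasses.asdict(r) for r in results)
    return pd.DataFrame(rows)


def _analysis_block(tn: pd.DataFrame, basis: str) -> dict[str, Any]:
    sub = tn[tn["basis"] == basis]
    paired = stats.paired_t_test(sub, cycle=1)
    ratio = stats.log_ratio_test(sub, cycle=1)
    frac, n_up, n_tot = stats.proportion_increased(sub, cycle=1)
    block = {
        "paired_t_cycle1": asdict(paired),
        "log_ratio_cycle1": asdict(ratio),
        "proportion_increased_cycle1": {
            "fraction": frac, "n_increased": n_up, "n_total": n_tot},
    }
    if sub["cycle"].nunique() > 1:
        block["lmm_all_cycles"] = asdict(stats.fit_two_level_lmm(sub))
        block["log_ratio_all_cycles"] = asdict(stats.log_ratio_test(sub, cycle=None))
    return block


def run_pipeline(config: RunConfig, seed: int | None = None) -> dict[str, Any]:
    """Run the requested stages and return (and persist) the full report."""
    cohort_cfg = config.cohort if seed is None else dataclasses.replace(
        config.cohort, seed=seed)
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "provenance": {
            "seed": cohort_cfg.seed,
            "config_hash": config_hash(cohort_cfg),
            "n_patients": cohort_cfg.n_patients,
            "n_cycles": cohort_cfg.n_cycles,
        }
    }

    if config.write_volumes and "generate" in config.stages:
        generate_cohort(cohort_cfg, out / "cohort")

    # Build phantoms in memory (deterministic: same seeds as generate_cohort).
    rand = generate_randomization(cohort_cfg.n_patients, cohort_cfg.seed)
    seeds = _patient_seeds(cohort_cfg)
    cohort_rng = np.random.default_rng(np.random.SeedSequence((cohort_cfg.seed, 1)))
    completed = _completed_cycles(cohort_cfg, cohort_rng)
    phantoms = [
        build_phantom(cohort_cfg, s, ia_lobe=a, patient_id=f"P{i + 1:02d}")
        for i, (a, s) in enumerate(zip(rand.assignments, seeds))
    ]
    covar_rng = np.random.default_rng(np.random.SeedSequence((cohort_cfg.seed, 2)))
    covariates = pd.DataFrame({
        "patient_id": [p.patient_id for p in phantoms],
        "ia_lobe": [p.ia_lobe for p in phantoms],
        "tumour_burden": [sum(v.volume_ml for v in p.lesion_vois.values())
                          for p in phantoms],
        "hypervascular": covar_rng.integers(0, 2, size=len(phantoms)),
    })
    covariates.to_csv(out / "covariates.csv", index=False)
    pd.DataFrame({
        "patient_id": [p.patient_id for p in phantoms],
        "ia_lobe": rand.assignments,
        "completed_cycles": completed,
    }).to_csv(out / "randomization.csv", index=False)

    if "quantify" in config.stages:
        tn = pd.concat(
            [quantify_phantom(p, n_cycles=c) for p, c in zip(phantoms, completed)],
            ignore_index=True,
        )
        tn.to_csv(out / "tn_ratios.csv", index=False)
    else:
        tn = pd.read_csv(out / "tn_ratios.csv")

    if "analyze" in config.stages:
        tn_cov = tn.merge(covariates, on="patient_id")
        analysis = {basis: _analysis_block(tn, basis) for basis in config.bases}
        if "mean" in config.bases:
            covs = {}
            for cov in ("hypervascular", "ia_lobe", "tumour_burden"):
                try:
                    covs[cov] = stats.covariate_test(
                        tn_cov[tn_cov["basis"] == "mean"], cov)
                except (ValueError, RuntimeError) as exc:
                    covs[cov] = f"not testable: {exc}"
            analysis["covariate_p_values"] = covs
        report["analysis"] = analysis

    if "respond" in config.stages:
        diam = pd.concat(
            [simulate_followup(p, cohort_cfg, cohort_rng) for p in phantoms],
            ignore_index=True)
        diam.to_csv(out / "diameters.csv", index=False)
        ia_lobes = dict(zip(covariates["patient_id"], covariates["ia_lobe"]))
        tables = response.classify_cohort_response(diam, ia_lobes)
        report["response"] = {}
        for timepoint, table in tables.items():
            # a single observed category carries no between-arm contrast
            p = (1.0 if table.shape[0] < 2
                 else stats.fisher_exact_rxc(table.to_numpy()))
            report["response"][timepoint] = {
                "table": table.to_dict(),
                "fisher_p": p,
            }

    if "toxicity" in config.stages:
        labs = pd.concat(
            [simulate_labs(p, cohort_cfg, cohort_rng) for p in phantoms],
            ignore_index=True)
        labs.to_csv(out / "labs.csv", index=False)
        events = []
        for pid, grp in labs.groupby("patient_id"):
            baseline = grp[grp["visit"] == 0].set_index("analyte")["value"]
            follow = {
                a: g["value"].to_numpy()
                for a, g in grp[grp["visit"] > 0].groupby("analyte")
            }
            events.extend(response.attribute_toxicity(
                baseline, follow, DEFAULT_GRADING_RULES, patient_id=pid))
        tox = response.toxicity_grade_table(events, response.ANALYTE_ORDER)
        report["toxicity"] = {
            "n_events": len(events),
            "grade_table": tox.to_dict(),
        }

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str) + "\n")
    render_tables(report, out)
    return report


def render_tables(report: dict[str, Any], outdir: Path) -> list[Path]:
    """Render the report blocks as CSV tables and a plain-text summary."""
    outdir = Path(outdir)
    written = []
    if "response" in report:
        for timepoint, block in report["response"].items():
            table = pd.DataFrame(block["table"])
            table["fisher_p"] = block["fisher_p"]
            path = outdir / f"response_{timepoint}.csv"
            table.to_csv(path)
            written.append(path)
    if "toxicity" in report:
        path = outdir / "toxicity_grades.csv"
        pd.DataFrame(report["toxicity"]["grade_table"]).to_csv(path)
        written.append(path)

    lines = [f"seed={report['provenance']['seed']}  "
             f"config={report['provenance']['config_hash']}"]
    analysis = report.get("analysis", {})
    for basis in ("mean", "peak"):
        if basis not in analysis:
            continue
        block = analysis[basis]
        pt = block["paired_t_cycle1"]
        lr = block["log_ratio_cycle1"]
        pi = block["proportion_increased_cycle1"]
        lines.append(
            f"[{basis}] cycle 1: mean difference {pt['mean_difference']:.2f} "
            f"(95% CI [{pt['ci_low']:.2f}, {pt['ci_high']:.2f}], p={pt['p_value']:.3f}); "
            f"geometric ratio {lr['geometric_ratio']:.3f} "
            f"(95% CI [{lr['ci_low']:.3f}, {lr['ci_high']:.3f}], p={lr['p_value']:.3f}); "
            f"{pi['n_increased']}/{pi['n_total']} increased"
        )
        if "lmm_all_cycles" in block:
            lm = block["lmm_all_cycles"]
            lines.append(
                f"[{basis}] all cycles LMM: arm effect {lm['fixed_effect_arm']:.3f} "
                f"(95% CI [{lm['ci_low']:.3f}, {lm['ci_high']:.3f}], "
                f"p={lm['p_value']:.3f})"
            )
    for timepoint, block in report.get("response", {}).items():
        lines.append(f"response {timepoint}: Fisher exact p={block['fisher_p']:.3f}")
    if "toxicity" in report:
        lines.append(f"treatment-emergent lab toxicities: "
                     f"{report['toxicity']['n_events']}")
    path = outdir / "report.txt"
    path.write_text("\n".join(lines) + "\n")
    written.append(path)
    return written
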