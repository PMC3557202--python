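"""Palmitate-induced ER-stress model suite and trajectory classification.

Bundles the progressive model versions of ATF4-dependent ER-stress
signaling in palmitate-treated liver cells:

``v1_literature``
    Literature network with every interaction on the same time scale
    (all delays 0).  Palmitate activates CREB1 through several parallel
    arms, while each eIF2a-kinase arm carries its own adaptation
    (desensitization) arm that cancels it almost immediately, so eIF2a
    and ATF4 barely move.  A variant without the PACT-PKR arm
    (``v1_literature_nopkr``) is bundled as well.
``v2_delays``
    Same wiring with measured response times encoded as edge delays:
    PKR responds promptly, PERK later, PKA much later, and the
    GADD34-PP1 negative feedback matures slowly.  eIF2a now shows a
    transient phosphorylation pulse, and the matured PP1 feedback
    drives ATF4 below control late in the window.
``v3_pp1_const``
    v2 plus the measured constraint that PP1 activity does not change:
    PP1 is clamped at control, removing the late suppression.
``v4_feedback_creb1`` / ``v4_feedback_atf4``
    v3 plus a positive transcriptional feedback onto the ATF4 promoter
    (CREB1 binding, or ATF4 binding its own promoter); either wiring
    sustains ATF4.
``v5_essential``
    The essential network: PACT-PKR, PERK, PKA and Ca2+ arms, both
    ATF4-promoter feedbacks, no p38/Ras shortcuts, no PP1 feedback.

Ten simulation steps correspond to roughly six hours of experimental
time; this constant is metadata for axis labeling only and never enters
the dynamics.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .ensemble import DEFAULT_HORIZON, DEFAULT_N_RUNS, EnsembleResult, InitDistribution, run_ensemble
from .network import NetworkSpec, parse_network
from .perturb import Perturbation, Scenario, compare_ensembles, load_scenario

__all__ = [
    "TrajectoryLabel",
    "classify_trajectory",
    "is_elevated",
    "model_path",
    "scenario_path",
    "load_model",
    "MODEL_VERSIONS",
    "STEPS_PER_SIX_HOURS",
    "run_figure_suite",
]

#: 10 simulation steps correspond to ~6 h of experimental time (axis
#: labeling only; the dynamics are dimensionless).
STEPS_PER_SIX_HOURS = 10

MODEL_VERSIONS = (
    "v1_literature",
    "v1_literature_nopkr",
    "v2_delays",
    "v3_pp1_const",
    "v4_feedback_creb1",
    "v4_feedback_atf4",
    "v5_essential",
)

DEFAULT_UP_THRESHOLD = 0.2
DEFAULT_EARLY_STEP = 5


def model_path(version: str) -> Path:
    """Filesystem path of a bundled network file."""
    if version not in MODEL_VERSIONS:
        raise KeyError(f"unknown model version {version!r}")
    return Path(resources.files("tridyn") / "models" / f"{version}.tsv")


def scenario_path(name: str) -> Path:
    """Filesystem path of a bundled scenario file."""
    p = Path(resources.files("tridyn") / "scenarios" / f"{name}.yaml")
    if not p.exists():
        raise KeyError(f"unknown scenario {name!r}")
    return p


def load_model(version: str) -> NetworkSpec:
    return parse_network(model_path(version))


@dataclass(frozen=True)
class TrajectoryLabel:
    """Qualitative class of a mean trajectory.

    ``sustained``: elevated (>= 1 + threshold) at both the early
    checkpoint and the final step.  ``transient``: elevated early but
    back under the elevation threshold (possibly below control) at the
    end.  ``suppressed``: at or below 1 - threshold at the end with no
    early elevation.  ``unchanged``: everything else.
    """

    label: str
    peak_step: int
    peak_deviation: float
    terminal_deviation: float


def classify_trajectory(
    mean_series,
    up_threshold: float = DEFAULT_UP_THRESHOLD,
    early_step: int = DEFAULT_EARLY_STEP,
    final_step: int | None = None,
) -> TrajectoryLabel:
    """Classify a per-step mean trajectory (values in [0, 2], control = 1)."""
    series = np.asarray(mean_series, dtype=float)
    if final_step is None:
        final_step = len(series) - 1
    if final_step >= len(series) or early_step > final_step:
        raise ValueError("series shorter than the classification window")
    if up_threshold <= 0:
        raise ValueError("up_threshold must be positive")
    dev = series - 1.0
    peak_step = int(np.argmax(dev[: final_step + 1]))
    peak = float(dev[peak_step])
    terminal = float(dev[final_step])
    early_up = series[early_step] >= 1.0 + up_threshold
    final_up = series[final_step] >= 1.0 + up_threshold
    final_down = series[final_step] <= 1.0 - up_threshold
    if early_up and final_up:
        label = "sustained"
    elif early_up:
        label = "transient"
    elif final_down:
        label = "suppressed"
    else:
        label = "unchanged"
    return TrajectoryLabel(
        label=label,
        peak_step=peak_step,
        peak_deviation=peak,
        terminal_deviation=terminal,
    )


def is_elevated(label: TrajectoryLabel) -> bool:
    """Whether a trajectory shows an early activation (sustained or transient)."""
    return label.label in ("sustained", "transient")


# ---------------------------------------------------------------------------
# Figure suite
# ---------------------------------------------------------------------------

_SUITE_SCENARIOS = {
    "v1_literature": "v1_literature_stim",
    "v1_literature_nopkr": "v1_literature_nopkr_stim",
    "v2_delays": "v2_delays_stim",
    "v3_pp1_const": "v3_pp1_const_stim",
    "v4_feedback_creb1": "v4_feedback_creb1_stim",
    "v4_feedback_atf4": "v4_feedback_atf4_stim",
    "v5_essential": "v5_essential_stim",
}


def _run_scenario(
    name: str,
    seed: int,
    n_runs: int | None,
    horizon: int | None,
    extra: list[Perturbation] | None = None,
) -> EnsembleResult:
    scn = load_scenario(scenario_path(name))
    if extra:
        scn.perturbations = list(scn.perturbations) + list(extra)
    if n_runs is not None:
        scn.n_runs = n_runs
    if horizon is not None:
        scn.horizon = horizon
    return scn.run(master_seed=seed)


def run_figure_suite(
    versions=MODEL_VERSIONS,
    output_dir: str | Path | None = None,
    n_runs: int | None = None,
    horizon: int | None = None,
    master_seed: int = 0,
    up_threshold: float = DEFAULT_UP_THRESHOLD,
    early_step: int = DEFAULT_EARLY_STEP,
) -> dict:
    """Run the full scenario suite and check the expected qualitative surface.

    For each requested model version, runs its stimulation scenario
    (palmitate clamped high), classifies the eIF2a/ATF4/CREB1 mean
    trajectories, runs the knockout comparisons on the essential model,
    and assembles a machine-readable report.  ``report["passed"]`` is
    False if any expected qualitative outcome is violated.  When
    ``output_dir`` is given, per-scenario ensemble TSVs and the JSON
    report are written there.

    ``n_runs``/``horizon`` default to each scenario file's own settings
    (5,000 runs, 40 steps).
    """
    versions = list(versions)
    unknown = set(versions) - set(MODEL_VERSIONS)
    if unknown:
        raise KeyError(f"unknown model version(s): {sorted(unknown)}")
    seeds = {v: (master_seed * 1000003 + i) % (2**31) for i, v in enumerate(MODEL_VERSIONS)}
    report: dict = {"master_seed": master_seed, "versions": {}, "checks": []}
    results: dict[str, EnsembleResult] = {}

    def check(name: str, ok: bool, detail: str) -> None:
        report["checks"].append({"check": name, "passed": bool(ok), "detail": detail})

    for v in versions:
        res = _run_scenario(_SUITE_SCENARIOS[v], seeds[v], n_runs, horizon)
        results[v] = res
        labels = {
            node: classify_trajectory(res.series(node), up_threshold, early_step)
            for node in ("eIF2a", "ATF4", "CREB1")
            if node in res.nodes
        }
        report["versions"][v] = {
            "n_runs": res.n_runs,
            "horizon": res.horizon,
            "labels": {node: asdict(lab) for node, lab in labels.items()},
        }

        if v in ("v1_literature", "v1_literature_nopkr"):
            check(f"{v}:eIF2a_not_sustained", labels["eIF2a"].label != "sustained",
                  f"eIF2a labeled {labels['eIF2a'].label}")
            check(f"{v}:ATF4_not_sustained", labels["ATF4"].label != "sustained",
                  f"ATF4 labeled {labels['ATF4'].label}")
            check(f"{v}:CREB1_elevated", is_elevated(labels["CREB1"]),
                  f"CREB1 labeled {labels['CREB1'].label}")
        elif v == "v2_delays":
            check("v2:eIF2a_transient", labels["eIF2a"].label == "transient",
                  f"eIF2a labeled {labels['eIF2a'].label}")
        elif v == "v3_pp1_const":
            check("v3:ATF4_not_suppressed", labels["ATF4"].label != "suppressed",
                  f"ATF4 labeled {labels['ATF4'].label}")
            check("v3:ATF4_not_sustained", labels["ATF4"].label != "sustained",
                  f"ATF4 labeled {labels['ATF4'].label}")
        elif v in ("v4_feedback_creb1", "v4_feedback_atf4"):
            check(f"{v}:ATF4_sustained", labels["ATF4"].label == "sustained",
                  f"ATF4 labeled {labels['ATF4'].label}")

    # Constraint-encoding comparison: clamping PP1 at control removes the
    # late feedback suppression, so terminal ATF4 rises from v2 to v3.
    if "v2_delays" in results and "v3_pp1_const" in results:
        t2 = float(results["v2_delays"].series("ATF4")[-1])
        t3 = float(results["v3_pp1_const"].series("ATF4")[-1])
        report["atf4_terminal"] = {"v2_delays": t2, "v3_pp1_const": t3}
        check("v3_gt_v2:ATF4_terminal", t3 > t2, f"v3 {t3:.3f} vs v2 {t2:.3f}")

    # Knockout comparisons on the essential model.
    if "v5_essential" in versions:
        ref = results["v5_essential"]
        ko: dict[str, EnsembleResult] = {}
        for tag, scn_name in (
            ("pkr_ko", "v5_pkr_knockout"),
            ("perk_ko", "v5_perk_knockout"),
            ("ca_ko", "v5_ca_knockout"),
            ("pathway_del", "v5_pathway_deletions"),
        ):
            ko[tag] = _run_scenario(scn_name, seeds["v5_essential"], n_runs, horizon)
            results[f"v5_essential:{tag}"] = ko[tag]

        step = early_step
        a_ref = float(ref.series("ATF4")[step])
        a_pkr = float(ko["pkr_ko"].series("ATF4")[step])
        a_perk = float(ko["perk_ko"].series("ATF4")[step])
        _, se_pkr = compare_ensembles(ref, ko["pkr_ko"], "ATF4")
        _, se_perk = compare_ensembles(ref, ko["perk_ko"], "ATF4")
        _, se_cross = compare_ensembles(ko["perk_ko"], ko["pkr_ko"], "ATF4")
        report["knockout_atf4_step5"] = {
            "unperturbed": a_ref,
            "pkr_ko": a_pkr,
            "perk_ko": a_perk,
            "se_pkr": float(se_pkr[step]),
            "se_perk": float(se_perk[step]),
            "se_cross": float(se_cross[step]),
        }
        check(
            "knockout_order:PKR_KO_lt_PERK_KO",
            a_pkr < a_perk - 3 * float(se_cross[step]),
            f"{a_pkr:.3f} vs {a_perk:.3f}",
        )
        check(
            "knockout_order:PERK_KO_lt_unperturbed",
            a_perk < a_ref - 3 * float(se_perk[step]),
            f"{a_perk:.3f} vs {a_ref:.3f}",
        )

        creb_ca = classify_trajectory(
            ko["ca_ko"].series("CREB1"), up_threshold, early_step
        )
        creb_del = classify_trajectory(
            ko["pathway_del"].series("CREB1"), up_threshold, early_step
        )
        report["versions"]["v5_essential"]["knockout_labels"] = {
            "ca_ko_CREB1": asdict(creb_ca),
            "pathway_del_CREB1": asdict(creb_del),
        }
        check("creb1_pathways:Ca_KO_CREB1_not_elevated", not is_elevated(creb_ca),
              f"CREB1 labeled {creb_ca.label}")
        check("creb1_pathways:pathway_del_CREB1_elevated", is_elevated(creb_del),
              f"CREB1 labeled {creb_del.label}")

    report["passed"] = all(c["passed"] for c in report["checks"])

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for key, res in results.items():
            fname = key.replace(":", "_") + ".tsv"
            res.write_tsv(
                out / fname,
                header_comment=f"scenario={key} seed={res.master_seed} n_runs={res.n_runs}",
            )
        (out / "suite_report.json").write_text(json.dumps(report, indent=2))
    return report
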