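"""Bone-strength score, fracture-risk classification, and the clinical report.

The score is femoral strength (N) divided by body weight (N, using
g = 9.81 N/kg).  Risk: value < 7.5 -> high; 7.5 <= value <= 8.5 -> moderate
(closed interval, so the boundary values are moderate); value > 8.5 -> low.
A "positive" call is the high-risk call (score below the cut), so
PPV = P(fracture | score < cut) and NPV = P(no fracture | score >= cut).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fe_solver import SimulationResult

__all__ = [
    "Patient",
    "BOSScore",
    "RiskCategory",
    "ScoreDatabase",
    "DatabaseStats",
    "compute_bos",
    "classify_risk",
    "database_stats",
    "render_report",
    "HIGH_RISK_CUT",
    "MODERATE_UPPER",
    "G_N_PER_KG",
    "CAUTION_TEXT",
]

HIGH_RISK_CUT = 7.5
MODERATE_UPPER = 8.5
G_N_PER_KG = 9.81
CAUTION_TEXT = (
    "Fracture localization by experimental fracturing in computer model "
    "does not necessarily coincide with metastatic location"
)


@dataclass(frozen=True)
class Patient:
    body_weight_kg: float
    age: float | None = None
    sex: str | None = None
    primary_tumor: str | None = None
    pain_score: float | None = None
    kps: float | None = None

    def __post_init__(self) -> None:
        if not self.body_weight_kg > 0:
            raise ValueError("body weight must be > 0 kg")
        if self.pain_score is not None and not (0 <= self.pain_score <= 10):
            raise ValueError("pain score must be in [0, 10]")
        if self.kps is not None and not (0 <= self.kps <= 100):
            raise ValueError("KPS must be in [0, 100]")


@dataclass(frozen=True)
class BOSScore:
    value: float
    strength_n: float
    weight_n: float


RiskCategory = str  # "high" | "moderate" | "low"


@dataclass
class ScoreDatabase:
    """Historic (score, fractured-within-6-months) records."""

    scores: np.ndarray
    fractured: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.fractured = np.asarray(self.fractured, dtype=bool)
        if self.scores.shape != self.fractured.shape:
            raise ValueError("scores and fracture flags must align")
        if np.any(self.scores <= 0):
            raise ValueError("database scores must be > 0")

    def __len__(self) -> int:
        return len(self.scores)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScoreDatabase":
        df = pd.read_csv(path)
        missing = {"bos_score", "fractured_6mo"} - set(df.columns)
        if missing:
            raise ValueError(f"database CSV missing columns: {sorted(missing)}")
        return cls(df["bos_score"].to_numpy(), df["fractured_6mo"].astype(bool).to_numpy())


@dataclass
class DatabaseStats:
    ppv: float | None
    npv: float | None
    sensitivity: float | None
    specificity: float | None
    n: int
    cut: float
    notes: list[str] = field(default_factory=list)

    def percentile(self, score: float, db: ScoreDatabase) -> float:
        return percentile_midrank(db.scores, score)


def percentile_midrank(values: np.ndarray, score: float) -> float:
    """Percentile of ``score`` within ``values`` using mid-rank ties."""
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("empty database")
    less = np.count_nonzero(values < score)
    equal = np.count_nonzero(values == score)
    return 100.0 * (less + 0.5 * equal) / len(values)


def compute_bos(strength_n: float, patient: Patient, g_n_per_kg: float = G_N_PER_KG) -> BOSScore:
    """Strength divided by body weight expressed in newtons."""
    if strength_n <= 0:
        raise ValueError("strength must be > 0 N")
    if g_n_per_kg <= 0:
        raise ValueError("g must be > 0")
    weight_n = patient.body_weight_kg * g_n_per_kg
    return BOSScore(value=strength_n / weight_n, strength_n=strength_n, weight_n=weight_n)


def classify_risk(
    score: BOSScore | float,
    low_high_cut: float = HIGH_RISK_CUT,
    moderate_upper: float = MODERATE_UPPER,
) -> RiskCategory:
    v = score.value if isinstance(score, BOSScore) else float(score)
    if v < low_high_cut:
        return "high"
    if v <= moderate_upper:  # boundary values are moderate (closed interval)
        return "moderate"
    return "low"


def database_stats(db: ScoreDatabase, cut: float = HIGH_RISK_CUT) -> DatabaseStats:
    """Predictive values of the high-risk call at ``cut``.

    Empty strata are flagged in ``notes`` and reported as None rather than
    propagating NaN.
    """
    if len(db) == 0:
        raise ValueError("empty database")
    below = db.scores < cut
    above = ~below
    frac = db.fractured
    notes: list[str] = []

    ppv = npv = sens = spec = None
    if below.any():
        ppv = float(np.count_nonzero(frac & below) / np.count_nonzero(below))
    else:
        notes.append("no scores below the cut: PPV undefined")
    if above.any():
        npv = float(np.count_nonzero(~frac & above) / np.count_nonzero(above))
    else:
        notes.append("no scores at/above the cut: NPV undefined")
    if frac.any():
        sens = float(np.count_nonzero(frac & below) / np.count_nonzero(frac))
    else:
        notes.append("no fractures in database: sensitivity undefined")
    if (~frac).any():
        spec = float(np.count_nonzero(~frac & above) / np.count_nonzero(~frac))
    else:
        notes.append("no non-fractures in database: specificity undefined")
    return DatabaseStats(ppv=ppv, npv=npv, sensitivity=sens, specificity=spec, n=len(db), cut=cut, notes=notes)


def render_report(
    score: BOSScore,
    category: RiskCategory,
    db: ScoreDatabase | None,
    simulation: SimulationResult | None,
    out_dir: str | Path,
    *,
    mesh=None,
    turnaround_days: int | None = None,
) -> dict:
    """Write report.json / report.html (plus figures) into ``out_dir``.

    Returns the JSON payload.  Missing simulation -> no weakest-location
    figure; empty/missing database -> percentile panel replaced by a notice.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    payload: dict = {
        "bos_score": score.value,
        "strength_n": score.strength_n,
        "weight_n": score.weight_n,
        "risk_category": category,
        "caution": CAUTION_TEXT,
        "turnaround_days": turnaround_days,
    }

    html = [
        "<html><head><title>Bone strength report</title></head><body>",
        f"<h1>Bone strength score: {score.value:.2f}</h1>",
        f"<p>Femoral strength {score.strength_n:.0f} N / body weight {score.weight_n:.0f} N</p>",
        f"<p>Fracture risk category: <b>{category}</b></p>",
    ]

    if db is not None and len(db) > 0:
        stats = database_stats(db)
        pct = percentile_midrank(db.scores, score.value)
        payload["percentile"] = pct
        payload["ppv"] = stats.ppv
        payload["npv"] = stats.npv
        payload["database_n"] = stats.n
        payload["database_notes"] = stats.notes
        html.append(f"<p>Percentile vs. database (n={stats.n}): {pct:.0f}</p>")
        html.append(
            f"<p>Predictive values at the {stats.cut} cut: "
            f"PPV {_fmt_pct(stats.ppv)}, NPV {_fmt_pct(stats.npv)}</p>"
        )
        fig, ax = plt.subplots(figsize=(6, 2.2))
        rng = np.random.default_rng(0)
        jitter = rng.uniform(-0.25, 0.25, size=len(db))
        colors = np.where(db.fractured, "tab:red", "tab:gray")
        ax.scatter(db.scores, jitter, c=colors, s=14, alpha=0.7)
        ax.axvline(HIGH_RISK_CUT, color="k", ls="--", lw=0.8)
        ax.axvline(MODERATE_UPPER, color="k", ls=":", lw=0.8)
        ax.scatter([score.value], [0], marker="v", s=120, c="tab:blue", zorder=5)
        ax.set_yticks([])
        ax.set_xlabel("bone strength score")
        fig.tight_layout()
        fig.savefig(out / "score_vs_database.png", dpi=120)
        plt.close(fig)
        html.append('<img src="score_vs_database.png" alt="score vs database"/>')
    else:
        payload["percentile"] = None
        payload["database_notice"] = "no score database available: percentile omitted"
        html.append("<p><i>No score database available: percentile panel omitted.</i></p>")

    if simulation is not None:
        payload["weakest_location_elements"] = [int(i) for i in simulation.plastic_elements_at_peak]
        payload["f_max_n"] = simulation.f_max_n
        if mesh is not None and len(simulation.plastic_elements_at_peak):
            cent = mesh.nodes[mesh.elements].mean(axis=1)
            fig = plt.figure(figsize=(4, 5))
            ax = fig.add_subplot(projection="3d")
            ax.scatter(*cent[:: max(1, len(cent) // 4000)].T, s=2, c="lightgray", alpha=0.3)
            hot = cent[simulation.plastic_elements_at_peak]
            ax.scatter(*hot.T, s=6, c="tab:red")
            ax.set_title("Weakest location")
            fig.savefig(out / "weakest_location.png", dpi=120)
            plt.close(fig)
            html.append('<img src="weakest_location.png" alt="weakest location"/>')
        html.append("<p><b>ATTENTION:</b> " + CAUTION_TEXT + "</p>")
    else:
        payload["weakest_location_elements"] = None
        payload["warning"] = "simulation result missing: weakest-location figure omitted"
        html.append("<p><i>Simulation result missing: weakest-location figure omitted.</i></p>")
        html.append("<p><b>ATTENTION:</b> " + CAUTION_TEXT + "</p>")

    html.append("</body></html>")
    (out / "report.html").write_text("\n".join(html))
    (out / "report.json").write_text(json.dumps(payload, indent=2))
    return payload


def _fmt_pct(x: float | None) -> str:
    return "n/a" if x is None else f"{100 * x:.0f}%"
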