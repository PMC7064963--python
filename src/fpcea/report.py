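"""Report tables, plots and run manifests.

Tables mirror the layout of the published evaluation: a cost block
(provider / user / total by arm, with the incremental column), an effects
block, an ICER table per effect measure, and a user-fee scenario table
(user totals and provider-perspective ICERs under 100% / 50% / 0% fees,
with the societal column for reference).  Monetary values are written at
full precision to CSV and formatted to 2 decimals in printed output.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from . import __version__
from .effects import EFFECT_MEASURES
from .model import ARMS, DecisionModel
from .uncertainty import TornadoEntry

__all__ = [
    "cost_table",
    "effect_table",
    "icer_table",
    "scenario_table",
    "plot_tornado",
    "plot_ce_plane",
    "plot_ceac",
    "write_manifest",
]

_MEASURE_LABELS = {
    "cyps": "Couple-years of protection",
    "pregnancies_averted": "Pregnancies averted",
    "abortions_averted": "Abortions averted",
    "under5_deaths_averted": "Under-5 mortalities averted",
    "maternal_deaths_averted": "Maternal mortalities averted",
    "dalys_averted": "DALYs averted",
}


def cost_table(model: DecisionModel, fee_fraction: float = 1.0) -> pd.DataFrame:
    """Cost block (US$ per 1000 clients): provider / user / total by arm."""
    out = {arm: model.arm_outcome(arm, fee_fraction=fee_fraction) for arm in ARMS}
    rows = {
        "provider": [out[a].cost.provider_net for a in ARMS],
        "user": [out[a].cost.user_total for a in ARMS],
        "total": [out[a].cost.societal for a in ARMS],
    }
    df = pd.DataFrame(rows, index=ARMS).T
    df.columns = ["intervention", "standard_care"]
    df["incremental"] = df["intervention"] - df["standard_care"]
    return df


def effect_table(model: DecisionModel) -> pd.DataFrame:
    """Effects block per 1000 clients, full precision."""
    out = {arm: model.arm_outcome(arm) for arm in ARMS}
    df = pd.DataFrame(
        {a: out[a].effects.as_dict() for a in ARMS}
    )
    df.columns = ["intervention", "standard_care"]
    df["incremental"] = df["intervention"] - df["standard_care"]
    df.index = [_MEASURE_LABELS[m] for m in df.index]
    return df


def icer_table(
    model: DecisionModel, perspective: str = "societal", fee_fraction: float = 1.0
) -> pd.DataFrame:
    """ICER per effect measure; undefined ratios carry their category."""
    res = model.evaluate(perspective=perspective, fee_fraction=fee_fraction)
    return pd.DataFrame(
        {
            "effect": [_MEASURE_LABELS[m] for m in EFFECT_MEASURES],
            "icer_usd_per_unit": [res.icers[m] for m in EFFECT_MEASURES],
            "category": [res.category[m] for m in EFFECT_MEASURES],
        }
    )


def scenario_table(
    model: DecisionModel, fee_fractions: tuple[float, ...] = (1.0, 0.5, 0.0)
) -> pd.DataFrame:
    """User totals and provider-perspective ICERs under user-fee scenarios."""
    rows = []
    for f in fee_fractions:
        out = {arm: model.arm_outcome(arm, fee_fraction=f) for arm in ARMS}
        res_p = model.evaluate(perspective="provider", fee_fraction=f)
        res_s = model.evaluate(perspective="societal", fee_fraction=f)
        rows.append(
            {
                "fee_fraction": f,
                "user_total_intervention": out["intervention"].cost.user_total,
                "user_total_standard_care": out["control"].cost.user_total,
                "user_total_incremental": out["intervention"].cost.user_total
                - out["control"].cost.user_total,
                "provider_icer_cyp": res_p.icers["cyps"],
                "provider_icer_daly": res_p.icers["dalys_averted"],
                "societal_total_intervention": out["intervention"].cost.societal,
                "societal_icer_daly": res_s.icers["dalys_averted"],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plots


def plot_tornado(
    entries: list[TornadoEntry], base_icer: float, path: str | Path, top: int = 15
) -> None:
    """Horizontal tornado: widest ICER swings on top, centered on the base."""
    shown = [e for e in entries if e.width > 0][:top]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(shown) + 1.5))
    y = range(len(shown))
    ax.barh(
        y,
        [e.high - e.low for e in shown],
        left=[e.low for e in shown],
        color="#4878a8",
        edgecolor="none",
    )
    ax.axvline(base_icer, color="k", lw=1, ls="--", label=f"base {base_icer:.2f}")
    ax.set_yticks(list(y), [e.name for e in shown])
    ax.invert_yaxis()
    ax.set_xlabel("ICER (US$ per DALY averted)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, metadata=_plot_metadata(path))
    plt.close(fig)


def plot_ce_plane(plane: dict, path: str | Path, effect_label: str = "DALYs averted") -> None:
    """Scatter of incremental (effect, cost) draws with threshold rays."""
    pts = plane["points"]
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(pts["delta_effect"], pts["delta_cost"], s=6, alpha=0.4, color="#4878a8")
    xmax = float(pts["delta_effect"].max()) * 1.05
    for key, style in (("lower", ":"), ("upper", "--")):
        lam = plane["rays"][key]
        ax.plot([0, xmax], [0, lam * xmax], "k" + style, lw=1, label=f"US${lam:.0f}/unit")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel(f"Incremental effect ({effect_label} per 1000 clients)")
    ax.set_ylabel("Incremental cost (US$ per 1000 clients)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, metadata=_plot_metadata(path))
    plt.close(fig)


def plot_ceac(
    curve: pd.DataFrame,
    path: str | Path,
    annotate: tuple[float, ...] = (58.0, 176.0),
    effect_label: str = "DALY averted",
) -> None:
    """Acceptability curve with probabilities marked at chosen thresholds."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["threshold"], curve["probability"], color="#4878a8")
    for lam in annotate:
        sub = curve.loc[(curve["threshold"] - lam).abs().idxmin()]
        ax.plot([sub["threshold"]], [sub["probability"]], "ko", ms=4)
        ax.annotate(
            f"{sub['probability']:.0%} at US${lam:.0f}",
            (sub["threshold"], sub["probability"]),
            textcoords="offset points",
            xytext=(6, -10),
            fontsize=8,
        )
    ax.set_xlabel(f"Cost-effectiveness threshold (US$ per {effect_label})")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, metadata=_plot_metadata(path))
    plt.close(fig)


def _plot_metadata(path: str | Path) -> dict | None:
    # strip volatile metadata so identical runs write identical files
    suffix = Path(path).suffix.lower()
    if suffix == ".svg":
        return {"Date": None}
    if suffix == ".png":
        return {"Software": None}
    return None


# ---------------------------------------------------------------------------
# manifest


def write_manifest(out_dir: str | Path, run_info: dict) -> Path:
    """Write ``manifest.json``: run configuration plus output hashes.

    Hashes cover tabular/JSON outputs; a rerun with the same configuration
    must reproduce them bit-exactly.
    """
    out_dir = Path(out_dir)
    hashes = {}
    for p in sorted(out_dir.glob("*")):
        if p.suffix in (".csv", ".yaml") and p.name != "manifest.json":
            hashes[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "package": "fpcea",
        "version": __version__,
        **run_info,
        "output_sha256": hashes,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
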