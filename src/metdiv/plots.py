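"""Plotting: Kaplan-Meier curves and ternary composition diagrams."""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .diversity import shannon_simplex_field  # noqa: E402
from .io import CELL_CLASSES  # noqa: E402
from .survival import km_estimate  # noqa: E402

_SQRT3_2 = np.sqrt(3.0) / 2.0


def km_plot(groups: dict, path, title: str = "", xlabel: str = "Months") -> None:
    """Kaplan-Meier curves for named groups of ``(times, events)``."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for label, (times, events) in groups.items():
        km = km_estimate(times, events)
        ax.step(km.times, km.survival, where="post", label=f"{label} (n={km.n})")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("Survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _barycentric(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # vertices: cancer (0,0), lymphocyte (1,0), stromal (0.5, sqrt(3)/2)
    x = p[:, 1] + 0.5 * p[:, 2]
    y = _SQRT3_2 * p[:, 2]
    return x, y


def ternary_plot(section_df, path, resolution: int = 60, title: str = "") -> None:
    """Section compositions on the 3-simplex over a Shannon-diversity field.

    Each point is one section; the background color is the theoretical
    Shannon diversity of the corresponding composition.
    """
    field = shannon_simplex_field(resolution)
    pf = field[[f"p_{c}" for c in CELL_CLASSES]].to_numpy()
    fx, fy = _barycentric(pf)
    fig, ax = plt.subplots(figsize=(6, 5.5))
    tc = ax.tricontourf(fx, fy, field["shannon"], levels=24, cmap="viridis")
    fig.colorbar(tc, ax=ax, label="Shannon diversity (nats)")
    ps = section_df[[f"p_{c}" for c in CELL_CLASSES]].to_numpy()
    sx, sy = _barycentric(ps)
    ax.plot(sx, sy, "k.", ms=5)
    for (vx, vy), name in zip([(0, 0), (1, 0), (0.5, _SQRT3_2)], CELL_CLASSES):
        ax.annotate(name, (vx, vy), textcoords="offset points",
                    xytext=(0, -12 if vy == 0 else 8), ha="center")
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def stability_plot(curve, path) -> None:
    """Stability curve: fraction of cohort vs % of resamples significant."""
    df = curve.as_frame()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(100 * df["fraction"], df["pct_significant"], "o-")
    ax.set_xlabel("% of cohort resampled")
    ax.set_ylabel("% of resamples significant")
    ax.set_ylim(-2, 102)
    ax.set_title(curve.analysis)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
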