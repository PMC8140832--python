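"""Static dashboard rendering: HTML pages, summary images, animated GIFs.

The dashboard is a self-contained directory of plain HTML, PNG and GIF files.
The landing page carries five links: center-level FPCA animations,
center-level rate-of-change animations, center-level mean predicted
trajectories, center-level mean predicted rate of change, and an (empty)
additional-displays page. Nine centers — three per size category — are shown.

Each center's animation follows a fixed multistage script: phenotypes in the
order late -> middle -> early, and within each phenotype the phases
highlight (observed/individual curves in the phenotype color), smooth
(individual fitted curves), collapse (fade into the phenotype mean curve).
Colors never vary: early = red, middle = yellow, late = green.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .benchmark import CenterProfile

__all__ = ["COLOR_MAP", "PHENOTYPE_ORDER", "PHASE_ORDER", "Frame", "AnimationScript",
           "build_animation_script", "select_display_centers", "render_dashboard"]

COLOR_MAP = {"early": "red", "middle": "yellow", "late": "green"}
PHENOTYPE_ORDER = ("late", "middle", "early")
PHASE_ORDER = ("highlight", "smooth", "collapse")
_GRAY = "0.75"

LINK_TITLES = [
    ("fpca_animations.html", "Center-Level FPCA Animations"),
    ("rate_animations.html", "Center-Level Rate-of-Change Animations"),
    ("mean_trajectories.html", "Center-Level Mean Predicted Trajectories"),
    ("mean_rates.html", "Center-Level Mean Predicted Rate of Change"),
    ("additional.html", "Additional Displays"),
]


@dataclass(frozen=True)
class Frame:
    phase: str       # highlight | smooth | collapse
    phenotype: str   # late | middle | early
    step: int        # 0..frames_per_phase-1 within the phase
    n_steps: int


@dataclass
class AnimationScript:
    """Deterministic ordered frame list for one center's animation."""

    center_id: str
    kind: str                      # "fpca" or "rate"
    frames: list[Frame]
    color_map: dict[str, str] = field(default_factory=lambda: dict(COLOR_MAP))

    @property
    def phase_blocks(self) -> list[tuple[str, str]]:
        seen, blocks = set(), []
        for f in self.frames:
            key = (f.phenotype, f.phase)
            if key not in seen:
                seen.add(key)
                blocks.append(key)
        return blocks


def build_animation_script(center_id: str, labels_present: list[str], *,
                           kind: str = "fpca",
                           frames_per_phase: int = 10) -> AnimationScript:
    """Frame list in the mandated order, restricted to phenotypes present."""
    present = [p for p in PHENOTYPE_ORDER if p in set(labels_present)]
    if not present:
        raise ValueError(f"center {center_id!r} has no patients")
    frames = [Frame(phase, pheno, s, frames_per_phase)
              for pheno in present
              for phase in PHASE_ORDER
              for s in range(frames_per_phase)]
    return AnimationScript(center_id=center_id, kind=kind, frames=frames)


def select_display_centers(profiles: list[CenterProfile], *, per_category: int = 3,
                           seed: int = 0) -> list[CenterProfile]:
    """Seeded random sample of per_category centers from each size category."""
    import warnings
    rng = np.random.default_rng(seed)
    chosen: list[CenterProfile] = []
    for cat in ("small", "medium", "large"):
        pool = sorted((p for p in profiles if p.size_category == cat),
                      key=lambda p: p.center_id)
        if len(pool) < per_category:
            warnings.warn(f"only {len(pool)} {cat} centers; taking all", stacklevel=2)
            chosen.extend(pool)
        else:
            idx = rng.choice(len(pool), size=per_category, replace=False)
            chosen.extend(pool[i] for i in sorted(idx))
    return chosen


# --------------------------------------------------------------------------
# plotting helpers

def _fig(figsize=(4.0, 3.0), dpi=70):
    fig, ax = plt.subplots(figsize=figsize, dpi=dpi)
    ax.set_xlabel("Age (years)")
    return fig, ax


def _fig_to_array(fig) -> np.ndarray:
    fig.canvas.draw()
    arr = np.asarray(fig.canvas.buffer_rgba())[:, :, :3].copy()
    plt.close(fig)
    return arr


def _axes_limits(kind: str, curves: pd.DataFrame) -> tuple[float, float]:
    vals = curves.to_numpy(dtype=float)
    lo, hi = float(np.nanmin(vals)), float(np.nanmax(vals))
    pad = 0.05 * (hi - lo + 1e-9)
    return lo - pad, hi + pad


def _render_animation_frames(script: AnimationScript, curves: pd.DataFrame,
                             raw_points: pd.DataFrame | None,
                             labels: pd.Series,
                             means: dict[str, np.ndarray],
                             grid: np.ndarray) -> list[np.ndarray]:
    """Rasterize one center's animation.

    ``curves``: fitted (or rate) curves for the center's patients on the grid;
    ``raw_points``: observed encounters (fpca animation only; rate animations
    start from the smooth individual curves, shown gray before clustering).
    ``means``: per-phenotype mean curve.
    """
    ylim = _axes_limits(script.kind, curves)
    ylabel = ("FEV1 (% predicted)" if script.kind == "fpca"
              else "Rate of change (% predicted/year)")
    images = []
    done: list[str] = []
    for fr in script.frames:
        fig, ax = _fig()
        ax.set_ylabel(ylabel)
        ax.set_xlim(grid[0], grid[-1])
        ax.set_ylim(*ylim)
        ax.set_title(f"Center {script.center_id}")
        frac = (fr.step + 1) / fr.n_steps
        # background: everything not yet reached, in gray
        for pid in curves.index:
            lab = labels.loc[pid]
            if lab != fr.phenotype and lab not in done:
                ax.plot(grid, curves.loc[pid], color=_GRAY, lw=0.6)
        # phenotypes already collapsed: their mean curve only
        for lab in done:
            if lab in means:
                ax.plot(grid, means[lab], color=COLOR_MAP[lab], lw=2.5)
        color = COLOR_MAP[fr.phenotype]
        members = [p for p in curves.index if labels.loc[p] == fr.phenotype]
        if fr.phase == "highlight":
            if script.kind == "fpca" and raw_points is not None:
                pts = raw_points[raw_points["patient_id"].isin(members)]
                ax.plot(pts["encounter_age"], pts["fev1pp"], ".", color=color,
                        ms=2.0, alpha=min(1.0, 0.3 + 0.7 * frac))
            else:
                for pid in members:
                    ax.plot(grid, curves.loc[pid], color=color, lw=0.8,
                            alpha=min(1.0, 0.3 + 0.7 * frac))
        elif fr.phase == "smooth":
            for pid in members:
                ax.plot(grid, curves.loc[pid], color=color, lw=1.0)
        else:  # collapse: individual curves shrink toward the mean
            mean = means.get(fr.phenotype)
            for pid in members:
                c = curves.loc[pid].to_numpy(dtype=float)
                ax.plot(grid, (1 - frac) * c + frac * mean, color=color,
                        lw=0.8, alpha=0.6)
            if mean is not None:
                ax.plot(grid, mean, color=color, lw=2.5, alpha=frac)
        images.append(_fig_to_array(fig))
        if fr.phase == "collapse" and fr.step == fr.n_steps - 1:
            done.append(fr.phenotype)
    return images


def _summary_png(profile: CenterProfile, grid: np.ndarray, kind: str,
                 path: Path) -> None:
    fig, ax = _fig()
    data = profile.mean_trajectory if kind == "fpca" else profile.mean_rate
    for lab in PHENOTYPE_ORDER:
        if lab in data:  # absent phenotypes draw no curve
            ax.plot(grid, data[lab], color=COLOR_MAP[lab], lw=2.0, label=lab)
    ax.set_ylabel("FEV1 (% predicted)" if kind == "fpca"
                  else "Rate of change (% predicted/year)")
    ax.set_title(f"Center {profile.center_id} ({profile.size_category})")
    ax.legend(fontsize=7, frameon=False)
    fig.savefig(path, metadata={"Software": None})
    plt.close(fig)


# --------------------------------------------------------------------------
# HTML templates (plain string substitution; no timestamps anywhere)

_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>body{{font-family:sans-serif;margin:2em}}
.grid{{display:flex;flex-wrap:wrap}}.tile{{margin:6px;text-align:center}}
.rowlabel{{font-weight:bold;margin-top:1em}}</style></head>
<body><h1>{title}</h1>
<p><a href="index.html">Back to landing page</a></p>
{body}
</body></html>
"""

_INDEX_BODY = """<p>Center-level benchmarking of rapid lung-function decline
phenotypes (early = red, middle = yellow, late = green).</p>
<ol>
{links}
</ol>
"""


def _tile(img: str, caption: str, href: str | None = None) -> str:
    inner = f'<img src="{img}" alt="{caption}">'
    if href:
        inner = f'<a href="{href}">{inner}</a>'
    return f'<div class="tile">{inner}<br>{caption}</div>'


def _rows_by_category(selected: list[CenterProfile]) -> list[tuple[str, list[CenterProfile]]]:
    return [(cat, [p for p in selected if p.size_category == cat])
            for cat in ("small", "medium", "large")]


def render_dashboard(profiles: list[CenterProfile],
                     curves: pd.DataFrame, derivatives: pd.DataFrame,
                     labels: pd.Series, centers: pd.Series, grid: np.ndarray,
                     records: pd.DataFrame, out_dir: str | Path, *, seed: int = 0,
                     frames_per_phase: int = 10, fps: int = 5) -> Path:
    """Write the full static dashboard tree; returns the output directory.

    Deterministic given its inputs and seed: identical HTML text on
    re-render, and no timestamps are embedded in images or GIFs.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create dashboard directory {out}: {e}") from e
    img_dir = out / "img"
    img_dir.mkdir(exist_ok=True)

    selected = select_display_centers(profiles, seed=seed)

    # summary thumbnails + GIFs per selected center
    for p in selected:
        _summary_png(p, grid, "fpca", img_dir / f"traj_{p.center_id}.png")
        _summary_png(p, grid, "rate", img_dir / f"rate_{p.center_id}.png")
        members = centers.index[centers == p.center_id]
        c_curves = curves.loc[curves.index.intersection(members)]
        c_deriv = derivatives.loc[derivatives.index.intersection(members)]
        c_labels = labels.loc[c_curves.index]
        present = sorted(set(c_labels))
        raw = records[records["patient_id"].isin(members)]
        for kind, data, means in (
            ("fpca", c_curves, p.mean_trajectory),
            ("rate", c_deriv, p.mean_rate),
        ):
            script = build_animation_script(p.center_id, present, kind=kind,
                                            frames_per_phase=frames_per_phase)
            frames = _render_animation_frames(
                script, data, raw if kind == "fpca" else None,
                c_labels, means, grid)
            iio.imwrite(img_dir / f"anim_{kind}_{p.center_id}.gif", frames,
                        duration=1000 // fps, loop=0)

    rows = _rows_by_category(selected)

    def grid_page(img_prefix: str, link_prefix: str | None) -> str:
        parts = []
        for cat, ps in rows:
            parts.append(f'<div class="rowlabel">{cat.capitalize()} centers</div>')
            parts.append('<div class="grid">')
            for p in ps:
                href = f"img/{link_prefix}{p.center_id}.gif" if link_prefix else None
                parts.append(_tile(f"img/{img_prefix}{p.center_id}.png",
                                   f"Center {p.center_id}", href))
            parts.append("</div>")
        return "\n".join(parts)

    pages = {
        "fpca_animations.html": grid_page("traj_", "anim_fpca_"),
        "rate_animations.html": grid_page("rate_", "anim_rate_"),
        "mean_trajectories.html": grid_page("traj_", None),
        "mean_rates.html": grid_page("rate_", None),
        "additional.html": "<p>No additional displays yet.</p>",
    }
    for (fname, title) in LINK_TITLES:
        (out / fname).write_text(_PAGE.format(title=title, body=pages[fname]))

    links = "\n".join(f'<li><a href="{fname}">{title}</a></li>'
                      for fname, title in LINK_TITLES)
    (out / "index.html").write_text(
        _PAGE.format(title="Rapid Lung-Function Decline Dashboard",
                     body=_INDEX_BODY.format(links=links)))
    return out
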