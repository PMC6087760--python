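"""Rendering of items to image files and the answer-key export.

Plot mode "A" (the default, used for calibration studies of this item type)
lays the stem row A, B, C and a question-mark placeholder above a 4 × 2 grid
of the eight figural options, with the two verbal options ("no answer is
correct", "I don't know") beneath; options are numbered in reading order
(left to right, top down).  Mode "B" stacks the options in a single column
and mode "C" is a compact two-panel variant (stem panel left, options panel
right).  Verbal options are available in English, German and Spanish.

Exports are deterministic: fixed figure sizes, fonts and PNG metadata make
re-runs byte-identical.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Polygon as MplPolygon

from .shape_model import FigureState, InvalidArgumentError, ShapeTemplate, build_template
from .item_builder import Item, ItemBank

__all__ = [
    "RenderConfig",
    "AnswerKeyRecord",
    "render_item",
    "export_bank",
    "switch_options",
    "read_answer_key",
]

VERBAL_OPTIONS = {
    "E": ("no answer is correct", "I don't know"),
    "D": ("Keine Antwort ist richtig", "Ich weiß es nicht"),
    "S": ("Ninguna respuesta es correcta", "No lo sé"),
}

_MODES = ("A", "B", "C")


@dataclass(frozen=True)
class RenderConfig:
    """Options controlling item plots and bank export."""

    mode: str = "A"
    language: str = "E"
    language_dir: Tuple[str, ...] = ("E", "D", "S")
    output_directory: Optional[Path] = None
    image_size: int = 900
    form_int: str = "A"
    form_ext: str = "A"
    write_key: bool = True
    image_format: str = "png"

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise InvalidArgumentError(f"unknown plot mode {self.mode!r}")
        if self.language not in VERBAL_OPTIONS:
            raise InvalidArgumentError(f"unknown language {self.language!r}")
        for lang in self.language_dir:
            if lang not in VERBAL_OPTIONS:
                raise InvalidArgumentError(f"unknown language {lang!r}")
        if self.image_format not in ("png", "svg"):
            raise InvalidArgumentError("image format must be 'png' or 'svg'")


@dataclass(frozen=True)
class AnswerKeyRecord:
    item_id: str
    correct_position: int
    rules_used: Tuple[str, ...]


# ---------------------------------------------------------------------------
# drawing primitives


def _transform(points: np.ndarray, template: ShapeTemplate, state: FigureState):
    """Main-shape orientation: optional x-flip then rotation about the
    centroid, both in template coordinates."""
    c = np.asarray(template.centroid)
    p = points - c
    if state.flipped:
        p = p * np.array([1.0, -1.0])
    ang = np.deg2rad(45.0 * (state.main_state - 1))
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    return p @ rot.T + c


def _draw_figure(ax, state: FigureState, template: ShapeTemplate) -> None:
    corners = np.asarray(template.corner_positions)

    # trapezium rotates about its own pivot before the whole-figure transform
    trap = np.asarray(template.trapezium)
    pv = np.asarray(template.trapezium_pivot)
    ang = np.deg2rad(45.0 * (state.trap_state - 1))
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    trap = (trap - pv) @ rot.T + pv

    hull_order = np.argsort(
        np.arctan2(*(corners - corners.mean(axis=0)).T[::-1])
    )
    outline = _transform(corners[hull_order], template, state)
    ax.add_patch(MplPolygon(outline, closed=True, fill=False, lw=1.4, ec="black"))

    pts = _transform(corners, template, state)
    for lid in sorted(state.present_lines):
        i, j = template.internal_lines[lid - 1]
        ax.plot(
            [pts[i - 1, 0], pts[j - 1, 0]],
            [pts[i - 1, 1], pts[j - 1, 1]],
            color="black",
            lw=0.9,
        )

    trap_t = _transform(trap, template, state)
    ax.add_patch(MplPolygon(trap_t, closed=True, fill=False, lw=1.2, ec="black"))

    (bc_center, bc_r) = template.broken_circle
    bc_c = _transform(np.asarray([bc_center]), template, state)[0]
    th = np.linspace(np.deg2rad(40), np.deg2rad(320), 60)
    ax.plot(bc_c[0] + bc_r * np.cos(th), bc_c[1] + bc_r * np.sin(th), color="black", lw=1.1)

    dot = pts[state.dot_corner - 1]
    ax.plot([dot[0]], [dot[1]], marker="o", ms=5, color="black")

    ax.set_xlim(-0.45, 1.45)
    ax.set_ylim(-0.45, 1.45)
    ax.set_aspect("equal")
    ax.axis("off")


def _panel(ax, label: str) -> None:
    ax.set_title(label, fontsize=9, pad=2)


def render_item(item: Item, config: RenderConfig = RenderConfig()) -> bytes:
    """Render one item to image bytes (PNG by default).

    The stem row shows A, B, C and the blank D; the option grid follows in
    reading order with the verbal options in the configured language.
    Rendering is pure: the same item and configuration yield identical bytes.
    """
    template = build_template(config.form_int, config.form_ext)
    verbal_9, verbal_idk = VERBAL_OPTIONS[config.language]
    dpi = 100
    size_in = config.image_size / dpi

    if config.mode == "A":
        fig = plt.figure(figsize=(size_in, size_in), dpi=dpi)
        gs = fig.add_gridspec(4, 4, height_ratios=[1.2, 1, 1, 0.25], hspace=0.35)
        stem_axes = [fig.add_subplot(gs[0, c]) for c in range(4)]
        opt_axes = [fig.add_subplot(gs[1 + r, c]) for r in range(2) for c in range(4)]
        text_y = 0.045
    elif config.mode == "B":
        fig = plt.figure(figsize=(size_in * 0.5, size_in * 1.9), dpi=dpi)
        gs = fig.add_gridspec(11, 2, hspace=0.4)
        stem_axes = [
            fig.add_subplot(gs[0, 0]),
            fig.add_subplot(gs[0, 1]),
            fig.add_subplot(gs[1, 0]),
            fig.add_subplot(gs[1, 1]),
        ]
        opt_axes = [fig.add_subplot(gs[2 + r, 0]) for r in range(8)]
        text_y = 0.02
    else:  # mode C: compact two-panel layout
        fig = plt.figure(figsize=(size_in * 1.4, size_in * 0.6), dpi=dpi)
        gs = fig.add_gridspec(2, 6, wspace=0.25, hspace=0.35)
        stem_axes = [fig.add_subplot(gs[r, c]) for r in range(2) for c in range(2)]
        opt_axes = [fig.add_subplot(gs[r, 2 + c]) for r in range(2) for c in range(4)]
        text_y = 0.03

    for ax, (state, label) in zip(
        stem_axes,
        [(item.stem.A, "A"), (item.stem.B, "B"), (item.stem.C, "C"), (None, "?")],
    ):
        if state is None:
            ax.text(0.5, 0.5, "?", fontsize=28, ha="center", va="center")
            ax.set_xlim(0, 1)
            ax.set_ylim(0, 1)
            ax.axis("off")
        else:
            _draw_figure(ax, state, template)
        _panel(ax, label)

    for k, (ax, state) in enumerate(zip(opt_axes, item.options.figural), start=1):
        _draw_figure(ax, state, template)
        _panel(ax, str(k))

    fig.text(0.5, text_y + 0.03, f"9. {verbal_9}", ha="center", fontsize=10)
    fig.text(0.5, text_y, f"10. {verbal_idk}", ha="center", fontsize=10)

    buf = io.BytesIO()
    if config.image_format == "png":
        fig.savefig(buf, format="png", metadata={"Software": "figana"})
    else:
        with matplotlib.rc_context({"svg.hashsalt": "figana"}):
            fig.savefig(buf, format="svg", metadata={"Date": None})
    plt.close(fig)
    return buf.getvalue()


def switch_options(item: Item, from_pos: int, to_pos: int) -> Item:
    """Swap two figural options; the answer key follows its option."""
    if not (1 <= from_pos <= 8 and 1 <= to_pos <= 8):
        raise InvalidArgumentError("option positions must lie in 1..8")
    fig = list(item.options.figural)
    comb = list(item.options.combination_by_slot)
    i, j = from_pos - 1, to_pos - 1
    fig[i], fig[j] = fig[j], fig[i]
    comb[i], comb[j] = comb[j], comb[i]
    correct = item.correct_position
    if correct == from_pos:
        correct = to_pos
    elif correct == to_pos:
        correct = from_pos
    options = replace(
        item.options, figural=tuple(fig), combination_by_slot=tuple(comb)
    )
    return replace(item, options=options, correct_position=correct)


def export_bank(
    bank: ItemBank,
    config: RenderConfig,
    which: Optional[Sequence[int]] = None,
) -> List[Path]:
    """Write one image per selected item per language plus the answer key.

    Returns the manifest of written paths.  ``which`` selects isomorph
    numbers (1-based); all items are exported by default.  The key file
    ``answer_key.csv`` holds one row per exported item: item id, correct
    position (reading order, 9 = "no answer is correct") and the general
    rules used, semicolon-joined.
    """
    if config.output_directory is None:
        raise InvalidArgumentError("export requires an output directory")
    out = Path(config.output_directory)
    if not out.is_dir():
        raise IOError(f"output directory {out} does not exist")
    if which is None:
        selected = list(bank.items)
    else:
        which = sorted(set(int(w) for w in which))
        bad = [w for w in which if not 1 <= w <= len(bank.items)]
        if bad:
            raise InvalidArgumentError(f"no such isomorph(s): {bad}")
        selected = [bank.items[w - 1] for w in which]
    if not selected:
        raise InvalidArgumentError("empty item selection")

    manifest: List[Path] = []
    for item in selected:
        for lang in config.language_dir:
            cfg = replace(config, language=lang)
            data = render_item(item, cfg)
            path = out / f"{item.item_id}_{lang}.{config.image_format}"
            path.write_bytes(data)
            manifest.append(path)
    if config.write_key:
        key_path = out / "answer_key.csv"
        with open(key_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["item_id", "correct_position", "rules_used"])
            for item in selected:
                writer.writerow(
                    [item.item_id, item.correct_position, ";".join(item.rules_used)]
                )
        manifest.append(key_path)
    return manifest


def read_answer_key(path) -> List[AnswerKeyRecord]:
    """Read back an exported answer key."""
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            records.append(
                AnswerKeyRecord(
                    item_id=row["item_id"],
                    correct_position=int(row["correct_position"]),
                    rules_used=tuple(r for r in row["rules_used"].split(";") if r),
                )
            )
    return records
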