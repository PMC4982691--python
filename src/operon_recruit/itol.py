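"""iTOL color-strip annotation export for trait overlays on trees.

The binary default follows the red/blue convention used for operon
association overlays: state 1 (associated) red, state 0 (elsewhere in the
genome) blue.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

from .model import DataError, TraitMap

DEFAULT_BINARY_PALETTE = {"1": "#ff0000", "0": "#0000ff"}

#: qualitative palette for categorical traits (architecture classes etc.)
CATEGORICAL_COLORS = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b",
    "#e377c2", "#7f7f7f", "#bcbd22", "#17becf", "#aec7e8", "#ffbb78",
)


def default_palette(traits: TraitMap) -> dict[str, str]:
    if set(traits.state_space) <= {"0", "1"}:
        return {s: DEFAULT_BINARY_PALETTE[s] for s in traits.state_space}
    if len(traits.state_space) > len(CATEGORICAL_COLORS):
        raise DataError("too many states for the default palette; supply one")
    return {
        s: CATEGORICAL_COLORS[i] for i, s in enumerate(traits.state_space)
    }


def export_colorstrip(
    traits: TraitMap,
    path: str | Path,
    palette: Mapping[str, str] | None = None,
    dataset_label: str = "trait",
) -> None:
    """Write an iTOL DATASET_COLORSTRIP file, one line per tip."""
    palette = dict(palette) if palette is not None else default_palette(traits)
    missing = set(traits.states.values()) - set(palette)
    if missing:
        raise DataError(f"palette missing states: {sorted(missing)}")
    lines = [
        "DATASET_COLORSTRIP",
        "SEPARATOR TAB",
        f"DATASET_LABEL\t{dataset_label}",
        "COLOR\t#999999",
        "LEGEND_TITLE\t" + dataset_label,
        "LEGEND_SHAPES\t" + "\t".join("1" for _ in traits.state_space),
        "LEGEND_COLORS\t" + "\t".join(palette[s] for s in traits.state_space),
        "LEGEND_LABELS\t" + "\t".join(traits.state_space),
        "DATA",
    ]
    for tip in sorted(traits.states):
        state = traits.states[tip]
        lines.append(f"{tip}\t{palette[state]}\t{state}")
    Path(path).write_text("\n".join(lines) + "\n")


def parse_colorstrip(path: str | Path) -> TraitMap:
    """Recover a TraitMap from an exported color-strip file (round-trip)."""
    states: dict[str, str] = {}
    in_data = False
    for line in Path(path).read_text().splitlines():
        if line.strip() == "DATA":
            in_data = True
            continue
        if not in_data or not line.strip():
            continue
        tip, _color, state = line.split("\t")
        states[tip] = state
    if not states:
        raise DataError(f"{path}: no DATA lines")
    return TraitMap.from_states(states)
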