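#!/usr/bin/env python
"""Regenerate the frozen per-preset initial conditions.

Paces each default preset for 100 beats at 1 Hz (dt = 0.02 ms) from a
generic resting guess and rewrites ``src/cardioinv/_initial_states.py``
with the final state.  Run after any change to the preset parameters.
"""

import sys
import textwrap
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from cardioinv import presets  # noqa: E402
from cardioinv.parameters import STATE_NAMES  # noqa: E402


def main() -> int:
    lines = [
        '"""Frozen per-preset initial conditions: the resting state of each default',
        'parameterization after 100 paced beats at 1 Hz (dt = 0.02 ms), regenerated',
        'with ``scripts/freeze_initial_states.py``."""',
        "",
        "# state order:",
        "# " + ", ".join(STATE_NAMES),
        "",
        "INITIAL_STATES: dict[str, list[float]] = {",
    ]
    for name in ("adult", "hipsc"):
        state = presets.compute_resting_state(presets.get_preset(name),
                                              beats=100)
        vals = ", ".join(f"{x:.10e}" for x in state.values)
        lines.append(f'    "{name}": [')
        for chunk in textwrap.wrap(vals, 76):
            lines.append("        " + chunk)
        lines.append("    ],")
    lines.append("}")
    out = ROOT / "src" / "cardioinv" / "_initial_states.py"
    out.write_text("\n".join(lines) + "\n")
    print(f"wrote {out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
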