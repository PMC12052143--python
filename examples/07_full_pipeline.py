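"""Run the whole analysis pipeline on one synthetic session.

Generates a 20-unit session, writes the session bundle and every stage's
output table under ./scratch/pipeline_demo, and prints the stage timings
and any inclusion-rule exclusions from the provenance record.
"""

import json
from pathlib import Path

from swmaze import run_pipeline

config = {
    "session": {"n_trials": 40, "neurons": 20},
    "stages": ["simulate", "behavior", "ratemaps", "decode-position",
               "goal-index", "decode-goal", "phase-locking",
               "classify-cells"],
    "goal_repeats": 10,
}
out = run_pipeline(config, Path("scratch/pipeline_demo"), seed=1)
prov = json.loads((out / "provenance.json").read_text())
print("outputs in:", out)
for stage, secs in prov["timings_s"].items():
    print(f"  {stage:>16}: {secs:7.2f} s")
if prov["exclusions"]:
    print("exclusions:")
    for e in prov["exclusions"]:
        print(f"  {e['stage']}/{e['unit']}: {e['rule']}")
# Re-running with the same config and seed reproduces every table
# byte-for-byte; the provenance records the config hash that guarantees it.
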