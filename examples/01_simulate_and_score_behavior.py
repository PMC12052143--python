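"""Generate a synthetic session and summarize task performance.

Builds a 40-trial delayed non-match-to-sample session with light delivered
in half the sample phases and a 30% lapse rate, then scores percent correct
per light condition.
"""

from swmaze import generate_session, score_performance
from swmaze.core import SessionConfig

config = SessionConfig(n_trials=40, p_error=0.3, light_phase="sample", seed=11)
session = generate_session(config)

perf = score_performance(session.trials)
for cond in ("off", "on"):
    e = perf.by_condition[cond]
    print(f"light-{cond}: {e['n_correct']}/{e['n_trials']} correct "
          f"({e['percent_correct']:.1f}%)")
print(f"difference score (off - on): {perf.difference_score:.1f} points")
# The difference score is the behavioral readout of silencing: positive
# values mean the animal performed worse with the light on.
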