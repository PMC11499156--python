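"""Build a conditioning protocol and inspect its event timings.

Constructs the explicitly-unpaired (safety) training session, prints the
tone-block (CS) and foot-shock (US) onsets, and the two derived interval
series: the variable CS-end-to-US interval (25-75 s range) and the
constant 60 s US-to-CS gap that define "explicitly unpaired" training.
"""

from freezekit import build_protocol, build_schedule, cs_us_intervals, us_cs_gaps

sched = build_schedule("safety_short", "training")
print("CS onsets (s): ", [tb.start_time for tb in sched.tone_blocks])
print("US onsets (s): ", [us.start_time for us in sched.shocks])
print("CS-end to US intervals (s):", cs_us_intervals(sched))
print("US to next-CS gaps (s):    ", us_cs_gaps(sched))
print()

# The intervals are the protocol's defining property: each tone ends 25-75 s
# before its shock (no predictive value), while every shock is followed by
# exactly 60 s of silence before the next tone.

for variant in ("safety_short", "fear_paired", "us_only_prolonged"):
    proto = build_protocol(variant)
    kinds = [f"{s.session_kind}({s.context})" for s in proto.sessions]
    print(f"{variant:20s} -> {' -> '.join(kinds)}")
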