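"""Four-stage thoracic pattern segmentation of a respiratory trace.

A sustained phonation shows: (1) inhalation to a local maximum just
before onset, (2) slow thoracic decline, (3) faster collapse, (4) a
plateau.  The generator embeds that pattern between resting tidal
cycles; the segmenter recovers the boundaries and per-stage slopes.
"""

from breathvoice import RespTrace, detect_resp_cycles, segment_stages
from breathvoice.synthdata import gen_respiratory_trace

signal, truth = gen_respiratory_trace(
    stage_durations=[1.5, 4.0, 1.5, 2.0],
    slopes=[0.5, -0.05, -0.4, 0.0],
    cycle_rest_hz=0.25, seed=1)
trace = RespTrace(signal)

cycles = detect_resp_cycles(trace)
print(f"respiratory cycles detected: {len(cycles)}")

seg = segment_stages(trace, truth["phonation_onset"])
t1, t2, t3 = seg.boundaries
print(f"stage 1 ends (pre-onset max):  {t1:6.2f} s   (truth {truth['stage1_end']:.2f})")
print(f"stage 2/3 breakpoint:          {t2:6.2f} s   (truth {truth['stage2_end']:.2f})")
print(f"stage 4 begins (plateau):      {t3:6.2f} s   (truth {truth['stage3_end']:.2f})")
print(f"slopes: {({k: round(v, 3) for k, v in seg.slopes.items()})}")
print(f"stages 2-3 merged (breathy-style fast depletion): {seg.merged_23}")
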