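"""Smoothed cepstral peak prominence across a breathiness ramp.

CPPS quantifies how sharply the cepstral peak at 1/f0 stands above the
quefrency trend: strong periodicity gives high values, aspiration noise
erodes them.  The loop below prints the monotone decline.
"""

from breathvoice import SynthParams, cpps
from breathvoice.synthdata import breathiness_to_oq, gen_voice

print("breathiness   CPPS (dB)")
for level in (0.0, 0.25, 0.5, 0.75, 1.0):
    voice = gen_voice(SynthParams(
        f0_hz=220.0, duration_s=2.0, breathiness_level=level,
        oq_target=breathiness_to_oq(level), sample_rate=16000.0, seed=3))
    value, n_frames = cpps(voice)
    print(f"   {level:4.2f}       {value:6.2f}   ({n_frames} frames)")
# Higher aspiration level -> weaker cepstral peak -> lower CPPS.
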