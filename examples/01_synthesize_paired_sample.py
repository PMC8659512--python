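"""Generate one paired microphone + EGG sample and inspect its pitch.

Builds a 2-second breathy trial, tracks f0 on both channels, and prints
the microphone-vs-EGG pitch difference (PD) in Hz and mel (MPD) — the
pitch-robustness measure of the pipeline.
"""

from breathvoice import SynthParams, TrialCondition, compare_pitch
from breathvoice.synthdata import gen_paired_sample

cond = TrialCondition("BSV", "medium", "sustained_comfortable")
params = SynthParams(f0_hz=220.0, duration_s=2.0, sample_rate=16000.0, seed=1)
sample = gen_paired_sample(cond, params)

cmp_result = compare_pitch(sample)
print(f"mean f0 (microphone): {cmp_result.mean_f0_cm:8.2f} Hz")
print(f"mean f0 (EGG):        {cmp_result.mean_f0_egg:8.2f} Hz")
print(f"PD  (CM - EGG):       {cmp_result.pd_hz:8.3f} Hz")
print(f"MPD (mel scale):      {cmp_result.mpd_mel:8.3f} mel")
# Both channels share one glottal source, so PD stays small even for a
# fully breathy trial; on real recordings PD grows with breathiness.
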