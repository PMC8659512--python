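"""Open quotient from the EGG channel by the DECOM and Howard methods.

The EGG waveform rises with vocal-fold contact; its derivative marks the
contacting (positive peak) and de-contacting (negative peak) instants.
DECOM measures the closed phase between those peaks against a
correlation-based period; Howard ends the closed phase where the EGG
falls through the 3:7 amplitude level.  Both should recover the
construction value.
"""

from breathvoice import SynthParams, oq_decom, oq_howard
from breathvoice.synthdata import gen_egg

print("target    DECOM    Howard   (cycles)")
for target in (0.50, 0.55, 0.60, 0.65):
    egg = gen_egg(SynthParams(f0_hz=110.0, duration_s=2.0, oq_target=target,
                              sample_rate=16000.0, seed=2))
    d = oq_decom(egg, 110.0)
    h = oq_howard(egg, 110.0)
    print(f" {target:.2f}    {d.mean_oq:.4f}   {h.mean_oq:.4f}   ({d.n_cycles})")
# Breathy phonation runs at a higher open quotient; the 0.50-0.65 span
# matches the class-mean range observed perceptually.
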