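"""End-to-end orchestration: per-sample feature extraction, synthetic
cohorts, and the rating-correlation analysis.

A feature row per 2-second sample carries PD/MPD (microphone-vs-EGG pitch
difference), CPPS, the two open quotients (DOQ, HOQ), ABI, and the two
composite indices CDH and CDH+ABI.  Features that cannot be measured are
flagged as NaN and excluded pairwise downstream, never silently zeroed.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np
import pandas as pd

from . import acoustic, cepstral, eggoq, indices, perception, pitchtrack, synthdata
from .core import MonoSignal, SignalError, VoiceSample

FEATURE_COLUMNS = ["pd_hz", "mpd_mel", "abs_pd_hz", "abs_mpd_mel", "cpps",
                   "doq", "hoq", "abi", "cdh", "cdh_abi"]


def extract_features(sample: VoiceSample,
                     cepstral_params: Optional[cepstral.CepstralParams] = None) -> dict:
    """One feature row from a paired CM+EGG sample.

    Partial failures (e.g. an unvoiced channel) flag the affected features
    as NaN; everything measurable is still computed.
    """
    row: dict = {"sample_id": sample.sample_id, "participant": sample.participant}
    params = cepstral_params or cepstral.CepstralParams()

    cmp_result = None
    try:
        cmp_result = pitchtrack.compare_pitch(sample)
    except SignalError:
        pass
    if cmp_result is not None and cmp_result.valid:
        row.update(pd_hz=cmp_result.pd_hz, mpd_mel=cmp_result.mpd_mel,
                   abs_pd_hz=cmp_result.abs_pd_hz, abs_mpd_mel=cmp_result.abs_mpd_mel,
                   mean_f0_cm=cmp_result.mean_f0_cm, mean_f0_egg=cmp_result.mean_f0_egg)
    else:
        row.update(pd_hz=np.nan, mpd_mel=np.nan, abs_pd_hz=np.nan,
                   abs_mpd_mel=np.nan, mean_f0_cm=np.nan, mean_f0_egg=np.nan)

    cpps_db, n_frames = cepstral.cpps(sample.cm, params)
    row["cpps"] = cpps_db
    row["cpps_frames"] = n_frames

    f0_hint = row["mean_f0_egg"]
    if not np.isfinite(f0_hint):
        f0_hint = row["mean_f0_cm"]
    if np.isfinite(f0_hint):
        for key, fn in (("doq", eggoq.oq_decom), ("hoq", eggoq.oq_howard)):
            try:
                series = fn(sample.egg, f0_hint)
                row[key] = np.nan if series.flagged else series.mean_oq
            except SignalError:
                row[key] = np.nan
        try:
            measures = acoustic.measure_all(sample.cm, cpps_db, f0_hint)
            row["abi"] = acoustic.abi(measures)
        except SignalError:
            row["abi"] = np.nan
    else:
        row.update(doq=np.nan, hoq=np.nan, abi=np.nan)

    if all(np.isfinite(row[k]) for k in ("cpps", "doq", "hoq")):
        row["cdh"] = indices.cdh(row["cpps"], row["doq"], row["hoq"])
        row["cdh_abi"] = (indices.cdh_abi(row["cpps"], row["doq"], row["hoq"], row["abi"])
                          if np.isfinite(row["abi"]) else np.nan)
    else:
        row["cdh"] = np.nan
        row["cdh_abi"] = np.nan
    return row


#: per-sample pitch bands of the trial mixture: 2-s excerpts come mostly
#: from sustained-comfortable trials, with low-tone / high-tone (and
#: glide) excerpts as minorities
F0_BANDS = (((200.0, 300.0), 0.6), ((150.0, 200.0), 0.2), ((300.0, 400.0), 0.2))


def _draw_f0(rng: np.random.Generator) -> float:
    u = rng.uniform()
    acc = 0.0
    for (lo, hi), p in F0_BANDS:
        acc += p
        if u <= acc:
            return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    lo, hi = F0_BANDS[-1][0]
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def gen_cohort(n_samples: int = 400, seed: int = 0, sample_rate: float = 16000.0,
               duration_s: float = 2.0, rater_noise_sd: float = 0.3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A synthetic cohort with a monotone breathiness structure.

    Breathiness levels are drawn uniformly on [0, 1]; each level sets the
    aspiration-noise gain and (affinely) the EGG open quotient, and the
    underlying perceptual degree is 4 x level, scored by two simulated
    raters.  Sung pitch is drawn from the trial-mixture bands (F0_BANDS)
    and intensity over +-6 dB, mirroring a protocol that crosses low,
    comfortable and high tones at three intensity levels.  Returns
    (features, ratings) DataFrames keyed by sample_id.
    """
    rng = np.random.default_rng(seed)
    feature_rows, rating_rows = [], []
    for i in range(n_samples):
        level = float(rng.uniform(0.0, 1.0))
        f0 = _draw_f0(rng)
        # within-singer open-quotient variability on top of the
        # breathiness map (pitch and intensity move OQ too)
        oq = float(np.clip(synthdata.breathiness_to_oq(level)
                           + 0.02 * rng.standard_normal(), 0.30, 0.85))
        params = synthdata.SynthParams(
            f0_hz=f0, duration_s=duration_s, breathiness_level=level,
            oq_target=oq,
            intensity_gain=float(rng.uniform(-6.0, 6.0)),
            sample_rate=sample_rate, seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        sample = VoiceSample(
            sample_id=f"{i:03d}",
            cm=synthdata.gen_voice(params),
            egg=synthdata.gen_egg(params),
            meta={"breathiness_level": level},
        )
        row = extract_features(sample)
        row["breathiness_level"] = level
        feature_rows.append(row)

        r1, r2 = synthdata.simulate_raters(4.0 * level, rater_noise_sd,
                                           seed=int(rng.integers(0, 2 ** 31 - 1)))
        rec = perception.average_and_classify(r1, r2, sample_id=row["sample_id"])
        rating_rows.append({"sample_id": rec.sample_id, "rater1": rec.rater1,
                            "rater2": rec.rater2, "average": rec.average,
                            "cls": rec.cls})
    return pd.DataFrame(feature_rows), pd.DataFrame(rating_rows)


def analyze(features: pd.DataFrame, ratings: pd.DataFrame,
            feature_names: Optional[list[str]] = None) -> dict:
    """The correlation analysis of one cohort.

    Returns a dict with the correlation table (Pearson and Spearman per
    feature), per-class descriptive means, the agreement distribution, and
    an index model refitted on this cohort's CPPS/DOQ/HOQ.
    """
    if ratings.empty:
        raise SignalError("empty ratings table")
    merged = features.merge(ratings, on="sample_id")
    if feature_names is None:
        feature_names = [c for c in FEATURE_COLUMNS if c in merged.columns]
    corr = perception.correlation_table(merged, merged["average"], feature_names)
    merged_desc = merged.rename(columns={})
    descriptives = perception.class_descriptives(
        merged_desc, class_col="cls",
        feature_names=[c for c in feature_names if c in merged.columns],
    )
    agreement = perception.agreement_distribution(
        zip(merged["rater1"], merged["rater2"]))
    fit_rows = merged.dropna(subset=["cpps", "doq", "hoq", "average"])
    model = indices.fit_index(fit_rows, ["cpps", "doq", "hoq"],
                              fit_rows["average"],
                              fitted_on=f"synthetic cohort n={len(fit_rows)}")
    return {"correlations": corr, "descriptives": descriptives,
            "agreement": agreement, "model": model}
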