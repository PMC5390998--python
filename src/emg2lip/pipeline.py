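"""Glue between raw recordings and the analysis-ready feature products."""

from __future__ import annotations

from . import signal_features as sf
from .evaluation import FeatureSetting

__all__ = ["featureize_recording"]


def featureize_recording(
    recording: sf.EMGRecording,
    setting: FeatureSetting,
    truncate_to: int = sf.TARGET_FEATURE_SAMPLES,
) -> tuple[sf.FeatureVector, sf.FeatureSeries]:
    """Full per-record feature pipeline at one setting.

    Configuration selection (for 16-electrode records), bandpass filtering,
    sliding-window feature extraction, truncation to the common length, and
    time averaging.  Returns the averaged vector and the truncated series.
    """
    rec = recording
    if rec.n_channels == 16:
        from .synthetic_data import configure_recording

        rec = configure_recording(rec, setting.configuration)
    elif rec.configuration != setting.configuration:
        raise sf.ConfigurationError(
            f"recording is {rec.configuration}; setting wants {setting.configuration}"
        )
    rec = sf.bandpass_filter(rec)
    series = sf.extract_feature(
        rec, setting.feature_type, setting.window_ms, s_lim=setting.s_lim
    )
    series = sf.truncate_series(series, truncate_to)
    return sf.average_features(series), series
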