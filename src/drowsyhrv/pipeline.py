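"""Convenience chaining of the pipeline stages over a cohort."""

from __future__ import annotations

import pandas as pd

from .ground_truth import IntervalLabel, adjust_ratings
from .hrv_features import BandDefinition, WindowSpec, extract_labeled_features
from .iodata import IBISeries
from .synthetic_data import SubjectBundle


def bundle_labels(bundle: SubjectBundle) -> list[IntervalLabel]:
    """Ground-truth labels of one subject: joint ratings adjusted by the
    subject's micro-sleep events."""
    return adjust_ratings(bundle.joint_ratings, bundle.events)


def extract_cohort_features(
    bundles: list[SubjectBundle],
    device: str,
    spec: WindowSpec = WindowSpec(),
    bands: BandDefinition = BandDefinition(),
) -> pd.DataFrame:
    """Labeled feature table over a cohort for one device."""
    frames = []
    for bundle in bundles:
        series: IBISeries = bundle.ecg if device == "ecg" else bundle.wristband
        labels = bundle_labels(bundle)
        frames.append(extract_labeled_features(series, labels, spec, bands))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
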