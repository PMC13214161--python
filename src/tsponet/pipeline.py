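"""End-to-end glue: scans -> features -> standardized features -> edges.

Feature standardization is done within tracer groups (all scans of a
tracer pooled, patients included), exactly once, before similarity
construction; the fitted scaling parameters are kept so held-out scans can
be transformed consistently.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import FeatureTable, extract_features
from .io import manifest_to_frame
from .network import build_similarity, robust_standardize, to_edge_vector

__all__ = ["extract_feature_tables", "standardize_by_tracer",
           "similarity_matrices", "edge_table"]


def extract_feature_tables(scans, records=None, **kwargs) -> list:
    """Kinetic feature tables for a list of scans (records supply
    dose/weight when given; matched by scan id)."""
    rec_map = {r.scan_id: r for r in records} if records else {}
    return [extract_features(s, rec_map.get(s.scan_id), **kwargs)
            for s in scans]


def standardize_by_tracer(tables, records):
    """Robust-standardize feature tables within each tracer group.

    Returns ``(standardized_tables, scalers)`` with tables in the input
    order and one fitted scaler per tracer.
    """
    tracer_of = {r.scan_id: r.tracer for r in records}
    by_tracer = {}
    for idx, t in enumerate(tables):
        by_tracer.setdefault(tracer_of[t.scan_id], []).append(idx)
    out = [None] * len(tables)
    scalers = {}
    for tracer, idxs in by_tracer.items():
        std, scaler = robust_standardize([tables[i] for i in idxs])
        scalers[tracer] = scaler
        for i, t in zip(idxs, std):
            out[i] = t
    return out, scalers


def similarity_matrices(tables_std) -> list:
    return [build_similarity(t) for t in tables_std]


def edge_table(scans, records, **kwargs):
    """Full front end: extract features, standardize per tracer, build
    similarity edges.

    Returns ``(edges, covariates)`` where ``edges`` is
    [n_scans x n_edges] in scan order and ``covariates`` the aligned
    manifest frame (indexed by scan id).
    """
    tables = extract_feature_tables(scans, records, **kwargs)
    tables_std, _ = standardize_by_tracer(tables, records)
    mats = similarity_matrices(tables_std)
    edges = np.vstack([to_edge_vector(m).values for m in mats])
    cov = manifest_to_frame(records)
    cov = cov.loc[[s.scan_id for s in scans]]
    return edges, cov
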