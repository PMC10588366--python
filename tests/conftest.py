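"""Shared fixtures.

``bench_pair`` runs the full bench-default paired simulation once per
session (the study conditions every benchmark-level test shares);
``small_cfg`` is a scaled-down scenario for fast unit tests of the same
code paths.
"""

import numpy as np
import pandas as pd
import pytest

import dashbench as db


@pytest.fixture(scope="session")
def small_cfg():
    return db.BenchConfig(
        n_cells=60, n_empty=150, n_genes=120, n_types=3, rare_type_prop=0.05,
        markers_per_type=10, cell_median_molecules=300,
        empty_median_molecules=60, total_reads=60_000, seed=7,
    ).validate()


@pytest.fixture(scope="session")
def bench_cfg():
    return db.load_scenario("bench-default")


@pytest.fixture(scope="session")
def bench_pair(bench_cfg):
    """Full bench-default paired experiment plus the derived call/partition
    objects used across the benchmark-level tests."""
    truth, base, untreated, dashed = db.simulate_paired(bench_cfg)
    feats = truth.features_frame()
    mu = db.collapse_umis(untreated, feats)
    md = db.collapse_umis(dashed, feats)
    calls_u = db.call_cells(mu, bench_cfg.n_cells)
    calls_d = db.call_cells(md, bench_cfg.n_cells)
    part = db.partition_barcodes(calls_u, calls_d)
    shared = sorted(part.shared)
    return {
        "cfg": bench_cfg, "truth": truth, "base": base,
        "untreated": untreated, "dashed": dashed,
        "matrix_u": mu, "matrix_d": md,
        "calls_u": calls_u, "calls_d": calls_d,
        "partition": part, "shared": shared,
        "metrics_u": db.per_cell_metrics(mu, bench_cfg.contaminant_name, shared),
        "metrics_d": db.per_cell_metrics(md, bench_cfg.contaminant_name, shared),
    }


@pytest.fixture(scope="session")
def small_pair(small_cfg):
    truth, base, untreated, dashed = db.simulate_paired(small_cfg)
    return {"cfg": small_cfg, "truth": truth, "base": base,
            "untreated": untreated, "dashed": dashed}
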