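import numpy as np
import pandas as pd
import pytest

import hypercell as hc


@pytest.fixture(scope="session")
def channel_table():
    return hc.default_channel_table()


@pytest.fixture(scope="session")
def sim_field():
    """One default simulated field plus its normalized stack and features."""
    stack, labels, truth = hc.simulate_field(hc.ImageSimSpec(seed=0))
    ns = hc.normalize_stack(stack)
    cells = hc.extract_cells(labels)
    features = hc.compute_features(ns, cells)
    return {"stack": stack, "normalized": ns, "labels": labels, "truth": truth,
            "cells": cells, "features": features}


@pytest.fixture(scope="session")
def ring_recovery():
    """Ring calls vs planted flags over 200 cells (10 fields, 50% ringed,
    planted log2 contrast 1.0, low noise)."""
    calls, truth = [], []
    for seed in range(100, 110):
        stack, labels, t = hc.simulate_field(hc.ImageSimSpec(seed=seed, ring_fraction=0.5))
        ns = hc.normalize_stack(stack)
        ft = hc.compute_features(ns, hc.extract_cells(labels))
        calls.append(ft["ring_call"].eq("ringed").to_numpy())
        truth.append(t["ringed"].to_numpy())
    return np.concatenate(calls), np.concatenate(truth)


@pytest.fixture(scope="session")
def gate_accuracies():
    """Planted-population recovery of the PCA + KDE gate over 10 seeds
    (3 pooled ring-free fields of 20 cells per seed)."""
    accuracies = []
    for seed in range(10):
        feats, pops = [], []
        for k in range(3):
            stack, labels, truth = hc.simulate_field(
                hc.ImageSimSpec(seed=seed * 10 + k, ring_fraction=0.0)
            )
            ns = hc.normalize_stack(stack)
            cells = hc.extract_cells(hc.threshold_segment(ns))
            feats.append(hc.compute_features(ns, cells))
            pops.append(truth["population"].to_numpy())
        X = pd.concat(feats)[[f"mean_ch{i:02d}" for i in range(1, 16)]].to_numpy()
        pop = np.concatenate(pops)
        res = hc.fit_spectral_pca(X)
        gate = hc.kde_gate(res.scores[:, :2], level=0.5, relative=True)
        g = gate.group_label
        accuracies.append(max((g == pop).mean(), (g == (3 - pop)).mean()))
    return accuracies


@pytest.fixture(scope="session")
def sim_counts():
    """117-cell count matrix with planted correlations and exon gradients."""
    rng = np.random.default_rng(42)
    feat = rng.uniform(300.0, 1200.0, 117)
    genes = [f"G{i:04d}" for i in range(1, 301)]
    planted = {g: [-0.5, 0.0, 0.5][i % 3] for i, g in enumerate(genes[:150])}
    spec = hc.CountsSimSpec(
        n_cells=117,
        n_genes=300,
        planted_rho=planted,
        exon_genes={"G0200": 4, "G0210": 1},
        planted_exon_gradients=(("G0200", 1, 1), ("G0200", 3, -1)),
        seed=11,
    )
    gene_df, exon_df, truth = hc.simulate_counts(spec, feat)
    feature = pd.Series(feat, index=gene_df.columns, name="area_px")
    return {"genes": gene_df, "exons": exon_df, "truth": truth,
            "feature": feature, "planted": planted}
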