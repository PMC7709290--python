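import numpy as np
import pandas as pd
import pytest

import stepblup as sb
from stepblup.simulate import SimConfig


def random_pedigree_records(rng, n_founders=20, n_generations=5, per_gen=40):
    """Random discrete-generation pedigree as raw (animal, sire, dam) rows."""
    records = [(f"f{i}", None, None) for i in range(n_founders)]
    prev = [f"f{i}" for i in range(n_founders)]
    for g in range(2, n_generations + 1):
        cur = []
        for k in range(per_gen):
            s, d = rng.choice(prev, size=2, replace=True)
            a = f"g{g}n{k}"
            records.append((a, str(s), str(d)))
            cur.append(a)
        prev = cur
    return records


def recursive_A_oracle(ped):
    """Entrywise recursion a(i,j) = 0.5*(a(j, s_i) + a(j, d_i)), independent
    of the tabular implementation."""
    n = ped.n
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam

    def a(i, j):
        if i < 0 or j < 0:
            return 0.0
        if i == j:
            s, d = sire[i], dam[i]
            return 1.0 + 0.5 * a(s, d) if (s >= 0 and d >= 0) else 1.0
        if j > i:
            i, j = j, i
        return 0.5 * (a(dam[i], j) + a(sire[i], j))

    import functools

    a = functools.lru_cache(maxsize=None)(a)
    for i in range(n):
        for j in range(i + 1):
            A[i, j] = A[j, i] = a(i, j)
    return A


def gls_blup_oracle(y_adj, Z, K, sigma_a2, sigma_e2):
    """Closed-form BLUP: u = sigma_a2 K Z' V^-1 (y - 1 mu_gls)."""
    n = len(y_adj)
    V = sigma_a2 * (Z @ K @ Z.T) + sigma_e2 * np.eye(n)
    Vinv = np.linalg.inv(V)
    one = np.ones(n)
    mu = float(one @ Vinv @ y_adj) / float(one @ Vinv @ one)
    u = sigma_a2 * K @ Z.T @ Vinv @ (y_adj - mu * one)
    return mu, u


@pytest.fixture(scope="session")
def small_sim():
    """One modest synthetic population shared across read-only tests."""
    cfg = SimConfig(
        founders=60,
        n_generations=5,
        sires_per_generation=10,
        dams_per_sire=4,
        n_snps=800,
        n_qtl=80,
        h2_true=(0.4,),
        genotyped_last_generations=2,
        genotyped_fraction=0.8,
        seed=11,
    )
    return sb.simulate_population(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
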