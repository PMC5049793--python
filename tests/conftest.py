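import numpy as np
import pytest

from cpmeta.sumstats import PanelKey, SummaryRecord


def make_record(snp_id="rs1", chromosome="1", position=1000, effect_allele="A",
                other_allele="G", eaf=0.3, beta=0.1, se=0.05, p_value=0.045,
                n=1000.0):
    return SummaryRecord(snp_id, chromosome, position, effect_allele,
                         other_allele, eaf, beta, se, p_value, n)


@pytest.fixture
def rng():
    return np.random.default_rng(20160912)


@pytest.fixture
def two_panel_keys():
    return [PanelKey("males", "height", 60586), PanelKey("females", "height", 73137)]


def random_corr(p, rng, strength=0.3):
    """Random well-conditioned correlation matrix."""
    a = rng.standard_normal((p, p + 3)) * strength
    cov = a @ a.T + np.eye(p)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


# ---- independent dense oracles (brute-force forms of the printed formulas) --

def oracle_s_hom(T, n, R, scheme="sqrt_n"):
    """Literal evaluation of the printed formula with explicit inverses:
    [e'(RW)^-1 T]^2 / [e'(WRW)^-1 e]."""
    T = np.asarray(T, float)
    n = np.broadcast_to(np.asarray(n, float), T.shape)
    w = {"sqrt_n": np.sqrt(n), "n": n, "unit": np.ones_like(n)}[scheme]
    W = np.diag(w)
    R = np.atleast_2d(R)
    e = np.ones_like(T)
    num = e @ np.linalg.inv(R @ W) @ T
    den = e @ np.linalg.inv(W @ R @ W) @ e
    return num * num / den


def oracle_s_tau(T, n, R, tau, scheme="sqrt_n"):
    """S(tau) with signed weights via explicit inverses; None if empty set."""
    T = np.asarray(T, float)
    n = np.broadcast_to(np.asarray(n, float), T.shape)
    act = np.abs(T) > tau
    if not act.any():
        return None
    t = T[act]
    base = {"sqrt_n": np.sqrt(n), "n": n, "unit": np.ones_like(n)}[scheme]
    w = base[act] * np.sign(t)
    W = np.diag(w)
    Rs = np.atleast_2d(R)[np.ix_(act, act)]
    e = np.ones_like(t)
    num = e @ np.linalg.inv(Rs @ W) @ t
    den = e @ np.linalg.inv(W) @ np.linalg.inv(Rs) @ np.linalg.inv(W) @ e
    return num * num / den


def oracle_s_het(T, n, R, scheme="sqrt_n"):
    """Exhaustive maximization over every threshold-reachable active set."""
    T = np.asarray(T, float)
    mags = np.unique(np.abs(T)[np.abs(T) > 0])
    best = 0.0 if mags.size == 0 else -np.inf
    for v in mags:
        val = oracle_s_tau(T, n, R, v - 1e-8, scheme)
        if val is not None and val > best:
            best = val
    return best
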