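"""MCMC convergence and efficiency diagnostics.

R-hat is the rank-normalized split potential scale reduction factor and
ESS the autocorrelation-based bulk effective sample size, both computed
by arviz (the modern recommendations); a classic (non-rank-normalized)
R-hat is available by flag.  Degenerate inputs — zero within-chain
variance everywhere — return an infinity sentinel rather than NaN so they
are visible in reports.  Reported ESS is capped at 10x the total retained
draw count (strongly antithetic chains can exceed the nominal draw count;
the cap keeps summaries finite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import arviz as az
import numpy as np
import pandas as pd

from .types import PosteriorSamples

__all__ = [
    "DiagnosticsReport",
    "gelman_rubin",
    "effective_sample_size",
    "summarize_diagnostics",
    "export_traces",
]

ESS_CAP_MULTIPLE = 10  # documented cap: ESS <= 10 * total draws


@dataclass
class DiagnosticsReport:
    per_parameter: pd.DataFrame       # parameter, rhat, ess
    summary: dict                     # avg/min/max of rhat and ess over betas

    def to_frame(self) -> pd.DataFrame:
        return self.per_parameter


def _stack_chains(chains) -> np.ndarray:
    """Coerce input to an (n_chains, n_draws) array."""
    arr = np.asarray(chains, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise ValueError("chains must be a sequence of 1-D draw arrays")
    return arr


def gelman_rubin(chains, rank_normalized: bool = True) -> float:
    """Split R-hat for one parameter from >= 2 chains.

    Returns the infinity sentinel (with a warning) when every chain has
    zero internal variance but the chains disagree — the between/within
    ratio is unbounded there.  An exactly constant parameter (all chains
    identical constants) returns 1.0.
    """
    arr = _stack_chains(chains)
    if arr.shape[0] < 2:
        raise ValueError("R-hat requires at least 2 chains")
    if arr.shape[1] < 4:
        raise ValueError("R-hat requires at least 4 draws per chain")
    within = arr.var(axis=1)
    if np.all(within == 0):
        if np.ptp(arr) == 0:
            return 1.0
        warnings.warn("zero within-chain variance: R-hat degenerate", stacklevel=2)
        return float("inf")
    method = "rank" if rank_normalized else "split"
    val = float(az.rhat(az.convert_to_dataset(arr), method=method)["x"])
    return val


def effective_sample_size(chains) -> float:
    """Autocorrelation-based (bulk) ESS combined across chains."""
    arr = _stack_chains(chains)
    if arr.shape[1] < 4:
        raise ValueError("ESS requires at least 4 draws per chain")
    if np.ptp(arr) == 0:
        warnings.warn("constant chains: ESS undefined", stacklevel=2)
        return float("nan")
    val = float(az.ess(az.convert_to_dataset(arr), method="bulk")["x"])
    return float(min(val, ESS_CAP_MULTIPLE * arr.size))


def _per_chain_views(samples: PosteriorSamples):
    """Split concatenated draws back into equal-length per-chain blocks."""
    ids = np.asarray(samples.chain_ids)
    uniq = list(dict.fromkeys(ids.tolist()))  # preserve order
    blocks = [np.flatnonzero(ids == c) for c in uniq]
    lengths = {len(b) for b in blocks}
    if len(lengths) != 1:
        raise ValueError("chains have unequal retained lengths")
    return blocks


def summarize_diagnostics(samples: PosteriorSamples) -> DiagnosticsReport:
    """R-hat and ESS for every beta coefficient and variance parameter.

    The summary block reports avg/min/max over the beta coefficients (the
    quantities of interest for variable selection).  With a single chain,
    R-hat is omitted (NaN) with a notice and ESS is still computed.
    """
    blocks = _per_chain_views(samples)
    n_chains = len(blocks)
    single = n_chains < 2
    if single:
        warnings.warn("single chain: R-hat omitted", stacklevel=2)

    def _matrix(draws_2d):
        # draws_2d: L x q  ->  (chains, per_chain, q)
        return np.stack([draws_2d[b] for b in blocks])

    names, rhats, esss = [], [], []
    beta_arr = _matrix(samples.beta_draws)
    ds = az.convert_to_dataset(beta_arr)
    if not single:
        rh_beta = np.asarray(az.rhat(ds, method="rank")["x"])
    else:
        rh_beta = np.full(samples.p, np.nan)
    es_beta = np.minimum(
        np.asarray(az.ess(ds, method="bulk")["x"]),
        ESS_CAP_MULTIPLE * samples.n_draws,
    )
    for j in range(samples.p):
        names.append(f"beta_{j}")
        rhats.append(float(rh_beta[j]))
        esss.append(float(es_beta[j]))

    extra = dict(samples.variance_draws)
    if samples.mu_draws is not None:
        extra["mu"] = samples.mu_draws
    for name, draws in extra.items():
        arr = np.stack([draws[b] for b in blocks])
        if np.ptp(arr) == 0:
            rhats.append(1.0 if single else 1.0)
            esss.append(float("nan"))
            names.append(name)
            continue
        dsv = az.convert_to_dataset(arr)
        rh = float("nan") if single else float(az.rhat(dsv, method="rank")["x"])
        es = float(min(float(az.ess(dsv, method="bulk")["x"]),
                       ESS_CAP_MULTIPLE * samples.n_draws))
        names.append(name)
        rhats.append(rh)
        esss.append(es)

    table = pd.DataFrame({"parameter": names, "rhat": rhats, "ess": esss})
    summary = {
        "rhat": {
            "avg": float(np.mean(rh_beta)) if not single else float("nan"),
            "min": float(np.min(rh_beta)) if not single else float("nan"),
            "max": float(np.max(rh_beta)) if not single else float("nan"),
        },
        "ess": {
            "avg": float(np.mean(es_beta)),
            "min": float(np.min(es_beta)),
            "max": float(np.max(es_beta)),
        },
    }
    return DiagnosticsReport(per_parameter=table, summary=summary)


def _parameter_series(samples: PosteriorSamples, name: str) -> np.ndarray:
    if name.startswith("beta_"):
        j = int(name.split("_", 1)[1])
        if j >= samples.p:
            raise KeyError(name)
        return samples.beta_draws[:, j]
    if name == "mu" and samples.mu_draws is not None:
        return samples.mu_draws
    if name in samples.variance_draws:
        return samples.variance_draws[name]
    available = [f"beta_0..beta_{samples.p - 1}"] + list(samples.variance_draws)
    if samples.mu_draws is not None:
        available.append("mu")
    raise KeyError(f"unknown parameter {name!r}; available: {available}")


def export_traces(
    samples: PosteriorSamples, parameters: list[str], path: str | Path
) -> list[Path]:
    """Write per-parameter trace tables (iteration, chain, value) as TSV."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    blocks = _per_chain_views(samples)
    written = []
    for name in parameters:
        series = _parameter_series(samples, name)
        frames = []
        for c, b in enumerate(blocks):
            frames.append(
                pd.DataFrame(
                    {
                        "iteration": np.arange(len(b)),
                        "chain": c,
                        "value": series[b],
                    }
                )
            )
        out = path / f"trace_{name}.tsv"
        pd.concat(frames, ignore_index=True).to_csv(out, sep="\t", index=False)
        written.append(out)
    return written
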