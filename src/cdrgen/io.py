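"""File formats, configuration, seeds, and the task driver.

Affinity training tables arrive as CSV with a ``sequence`` column and one or
more Kd columns (nM); replicate measurements are averaged and rows without
any measurement are dropped with a logged count. All task randomness flows
from a single master seed through ``numpy.random.SeedSequence`` derivation;
every run directory carries a JSON manifest with the resolved config, seed
and a config hash so outputs are self-describing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import baselines, ebm, gflownet, gp, humanness, landscape as lsmod, mcmc, pareto, solubility
from .seqspace import AB14_CDR_WT, SearchConstraints, WildType, hamming

log = logging.getLogger(__name__)

#: Named parameter profiles matching the published run conditions.
PROFILES = {
    "cb119": {"inv_temperature": 20.0, "weights": [0.85, 0.875, 0.9, 0.95, 1.0],
              "betas": [-1.0, 0.0, 1.0, 2.0], "d_lim": 6, "budget": 1000},
    "synthetic": {"inv_temperature": 10.0, "weights": [0.85, 1.0],
                  "betas": [-1.0, 0.0, 1.0, 2.0], "d_lim": 6, "budget": 500},
}


def load_affinity_csv(path, replicate_policy: str = "mean") -> pd.DataFrame:
    """Load a (sequence, Kd replicates) CSV into a scored table with faff.

    Kd columns are every column whose name starts with ``kd`` (nM units).
    ``mean`` averages replicates ignoring missing values; ``error`` raises on
    any missing replicate. Rows with no measurement at all are dropped and
    counted in the log.
    """
    df = pd.read_csv(path)
    if "sequence" not in df.columns:
        raise ValueError("affinity CSV needs a 'sequence' column")
    kd_cols = [c for c in df.columns if c.lower().startswith("kd")]
    if not kd_cols:
        raise ValueError("affinity CSV needs at least one Kd column (kd*)")
    kd = df[kd_cols].apply(pd.to_numeric, errors="coerce")
    if replicate_policy == "error" and kd.isna().any().any():
        bad = df.index[kd.isna().any(axis=1)].tolist()
        raise ValueError(f"missing replicate measurements at rows {bad}")
    mean_kd = kd.mean(axis=1)
    dropped = int(mean_kd.isna().sum())
    if dropped:
        log.info("dropped %d rows with no Kd measurement", dropped)
    out = df.loc[mean_kd.notna(), ["sequence"]].copy()
    out["kd_nm"] = mean_kd[mean_kd.notna()].to_numpy()
    out["faff"] = [gp.kd_to_affinity(k) for k in out["kd_nm"]]
    out.attrs["n_dropped"] = dropped
    return out.reset_index(drop=True)


def split_dataset(df: pd.DataFrame, fractions, seed: int = 0) -> list[pd.DataFrame]:
    """Disjoint seed-reproducible splits; the last split takes the remainder
    only if the fractions sum to 1."""
    fracs = list(fractions)
    if sum(fracs) > 1 + 1e-9:
        raise ValueError("fractions must sum to at most 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(df))
    splits, start = [], 0
    for i, f in enumerate(fracs):
        stop = len(df) if (i == len(fracs) - 1 and abs(sum(fracs) - 1) < 1e-9) else start + int(round(f * len(df)))
        splits.append(df.iloc[perm[start:stop]].reset_index(drop=True))
        start = stop
    return splits


def expand_sweep(weights, betas) -> list[dict]:
    """Cartesian (w, beta) condition grid, e.g. 5 weights x 4 betas -> 20."""
    return [{"w": float(w), "beta": float(b)} for w in weights for b in betas]


def write_fasta(path, seqs, ids=None) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    ids = ids or [f"candidate_{i + 1}" for i in range(len(seqs))]
    records = [SeqRecord(Seq(s), id=i, description="") for s, i in zip(seqs, ids)]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[str]:
    from Bio import SeqIO

    return [str(r.seq) for r in SeqIO.parse(str(path), "fasta")]


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# task driver
# ---------------------------------------------------------------------------


def _build_energy(config: dict, gp_model, encoder):
    beta = float(config.get("beta", 0.0))
    w = float(config.get("w", 1.0))
    inv_T = float(config.get("inv_temperature", 10.0))
    sol_fn = solubility.make_solubility_fn()

    def aff_fn(seq: str) -> float:
        return float(gp_model.acquisition(encoder(seq)[None, :], beta)[0])

    prior_kind = config.get("prior", "uniform")
    prior = humanness.UniformPrior() if prior_kind == "uniform" else prior_kind
    return ebm.affinity_solubility_energy(aff_fn, sol_fn, w, inv_T, prior), aff_fn, sol_fn


def _task_synth_bench(config: dict, seed: int, outdir: Path) -> dict:
    """Landscape -> dataset -> GP fit -> MCMC -> Pareto report, end to end."""
    wt = WildType(config.get("wt", AB14_CDR_WT))
    spec = lsmod.LandscapeSpec.named(config.get("landscape", "simple"))
    ls = lsmod.sample_landscape(spec, wt, seed)
    data = lsmod.build_dataset(
        ls,
        n_double=int(config.get("n_double", 2100)),
        n_triple=int(config.get("n_triple", 11900)),
        seed=seed + 1,
    )
    train_frac = float(config.get("train_fraction", 0.3))
    train, _ = split_dataset(data, [train_frac, 1 - train_frac], seed=seed + 2)
    n_train = min(len(train), int(config.get("max_train", 1500)))
    train = train.head(n_train)
    model, encoder = gp.fit_gp_on_sequences(
        train["sequence"], train["observed_faff"], steps=int(config.get("gp_steps", 200))
    )
    target, aff_fn, sol_fn = _build_energy(config, model, encoder)
    n_steps = int(config.get("n_steps", 2000))
    cfg = mcmc.MCMCConfig(
        n_chains=int(config.get("n_chains", 4)),
        n_steps=n_steps,
        d_lim=int(config.get("d_lim", 6)),
        extension_steps=int(config.get("extension_steps", n_steps)),
        max_extensions=int(config.get("max_extensions", 1)),
        seed=seed + 3,
    )
    pooled, report = mcmc.sample_posterior_sequences(cfg, target, wt)
    uniq = sorted(set(pooled))
    aff = np.array([aff_fn(s) for s in uniq])
    sol = np.array([sol_fn(s) for s in uniq])
    cs = pareto.CandidateSet.from_arrays(uniq, aff, sol)
    cand = cs.report()
    cand["true_faff"] = ls.evaluate_many(list(cand["sequence"]))
    cand.to_csv(outdir / "candidates.csv", index=False)
    B = min(int(config.get("budget", 500)), len(cand))
    top = cand.head(B)
    return {
        "n_candidates": len(cand),
        "mcmc": report,
        "top_mean_true_faff": float(top["true_faff"].mean()),
        "train_best_mean_true_faff": float(
            train.nlargest(min(B, len(train)), "observed_faff")["true_faff"].mean()
        ),
    }


def _task_sample_mcmc(config: dict, seed: int, outdir: Path) -> dict:
    wt = WildType(config.get("wt", AB14_CDR_WT))
    train = pd.read_csv(config["train_csv"])
    model, encoder = gp.fit_gp_on_sequences(
        train["sequence"], train[config.get("target_col", "faff")],
        steps=int(config.get("gp_steps", 200)),
    )
    target, aff_fn, sol_fn = _build_energy(config, model, encoder)
    n_steps = int(config.get("n_steps", 20000))
    cfg = mcmc.MCMCConfig(
        n_chains=int(config.get("n_chains", 8)),
        n_steps=n_steps,
        d_lim=int(config.get("d_lim", 6)),
        extension_steps=int(config.get("extension_steps", n_steps)),
        max_extensions=int(config.get("max_extensions", 3)),
        seed=seed,
    )
    pooled, report = mcmc.sample_posterior_sequences(cfg, target, wt)
    uniq = sorted(set(pooled))
    df = pd.DataFrame(
        {
            "sequence": uniq,
            "acq": [aff_fn(s) for s in uniq],
            "sol_pred": [sol_fn(s) for s in uniq],
            "n_mutations": [hamming(s, wt.sequence) for s in uniq],
        }
    )
    df.to_csv(outdir / "samples.csv", index=False)
    write_fasta(outdir / "samples.fasta", list(df["sequence"]))
    return {"n_unique": len(uniq), "mcmc": report}


def _task_fit_gp(config: dict, seed: int, outdir: Path) -> dict:
    table = load_affinity_csv(config["train_csv"]) if config.get("kd_input", True) else pd.read_csv(config["train_csv"])
    model, _ = gp.fit_gp_on_sequences(
        table["sequence"], table["faff"], steps=int(config.get("gp_steps", 600))
    )
    p = model.params
    checkpoint = {
        "delta": p.delta, "lam": p.lam, "sigma_n": p.sigma_n, "C": p.C,
        "n_train": model.n, "seed": seed,
    }
    (outdir / "gp_params.json").write_text(json.dumps(checkpoint, indent=2))
    return checkpoint


def run(config: dict, outdir, seed: int | None = None) -> dict:
    """Dispatch a task config; writes a manifest and returns the summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0)) if seed is None else int(seed)
    task = config.get("task")
    tasks = {
        "synth-bench": _task_synth_bench,
        "sample-mcmc": _task_sample_mcmc,
        "fit-gp": _task_fit_gp,
    }
    if task not in tasks:
        raise ValueError(f"unknown task {task!r}; available: {sorted(tasks)}")
    manifest = {
        "task": task, "seed": seed, "config": config,
        "config_hash": config_hash(config), "status": "incomplete",
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    try:
        summary = tasks[task](config, seed, outdir)
    except Exception:
        manifest["status"] = "failed"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    manifest["status"] = "complete"
    manifest["summary"] = summary
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return summary
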