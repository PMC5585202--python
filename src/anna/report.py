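"""Pipeline orchestration and publication-style reporting.

Ties the stages together: read networks → compute the six whole-network
parameters → detect and validate connectivity modules → (optionally)
test phylogenetic signal and reconstruct ancestral states of each
parameter on a user-supplied tree.  Reports are plain CSV/JSON with the
full run configuration echoed into the manifest so any report can be
reproduced from itself.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community import detect_modules
from .network import read_adjacency_csv, read_tissue_map
from .parameters import compute_all, round_half_away
from .phylo import ancestral_states, blomberg_k, fit_pagel_lambda, phenogram_export, read_newick

__all__ = ["RunConfig", "run_full_pipeline", "summarize_group", "quartile_band"]

log = logging.getLogger("anna")

REPORT_COLUMNS = ["Taxa", "N", "K", "D", "C", "L", "H", "M"]


@dataclass
class RunConfig:
    """Fully serializable settings for one pipeline run."""

    networks: list[str] = field(default_factory=list)
    tree: str | None = None
    tissue_map: str | None = None
    traits: list[str] = field(default_factory=lambda: ["N", "K", "D", "C", "L", "H", "M"])
    walktrap_steps: int = 3
    sd: str = "population"  # heterogeneity estimator: population | sample
    clustering: str = "include-zeros"  # include-zeros | exclude-low-degree
    jackknife: str = "fixed"  # fixed | redetect
    n_permutations: int = 1000
    seed: int = 0
    out_dir: str = "anna_out"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


def _file_hash(path: str | Path) -> str:
    return hashlib.md5(Path(path).read_bytes()).hexdigest()


def run_full_pipeline(cfg: RunConfig) -> dict[str, str]:
    """Run every stage and write the report bundle.

    Writes into ``cfg.out_dir``:

    * ``parameters.csv`` — one row per network, Taxa/N/K/D/C/L/H/M with
      ratios rounded half-away-from-zero to 3 decimals,
    * ``parameters_raw.csv`` — the same values at full precision,
    * ``modules_<taxon>.json`` and ``modules_<taxon>.csv`` — module
      report and node → module table per network,
    * ``phylosig.csv`` and ``phenogram_<trait>.csv`` — when a tree is
      supplied,
    * ``manifest.json`` — config, seed, package version and input
      hashes.

    Any stage failure raises with the stage name and offending input.
    Returns a name → path map of everything written.
    """
    if not cfg.networks:
        raise ValueError("at least one network is required")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    tissues = read_tissue_map(cfg.tissue_map) if cfg.tissue_map else None
    include_low = cfg.clustering == "include-zeros"

    raw_rows = []
    for path in cfg.networks:
        try:
            net = read_adjacency_csv(path, tissue_map=tissues)
            log.info("stage=read input=%s hash=%s N=%d K=%d",
                     path, _file_hash(path), net.n_nodes, net.n_edges)
            params = compute_all(net, include_low_degree=include_low, sd=cfg.sd)
            part = detect_modules(net, t=cfg.walktrap_steps, jackknife=cfg.jackknife)
        except Exception as exc:
            raise RuntimeError(f"stage 'network' failed on input {path!r}: {exc}") from exc
        assert abs(params.D - 2 * params.K / (params.N * (params.N - 1))) < 1e-12
        raw_rows.append({"Taxa": net.name, **params.as_dict(), "M": part.M,
                         "Q": part.Q, "Q_se": part.Q_se})

        mod_report = {
            "taxon": net.name,
            "M": part.M,
            "Q": part.Q,
            "Q_se": part.Q_se,
            "modules": [
                {
                    "id": s.module,
                    "nodes": part.members(s.module),
                    "internal": s.internal_links,
                    "external": s.external_links,
                    "wilcoxon_p": s.wilcoxon_p,
                }
                for s in part.module_stats
            ],
        }
        stem = f"modules_{net.name}" if net.name else f"modules_{Path(path).stem}"
        jpath = out / f"{stem}.json"
        jpath.write_text(json.dumps(mod_report, indent=2) + "\n", encoding="utf-8")
        cpath = out / f"{stem}.csv"
        pd.DataFrame(
            {"node": list(part.assignment), "module": list(part.assignment.values())}
        ).to_csv(cpath, index=False)
        written[f"{stem}.json"] = str(jpath)
        written[f"{stem}.csv"] = str(cpath)
        log.info("stage=modules input=%s M=%d Q=%.4f", path, part.M, part.Q)

    raw = pd.DataFrame(raw_rows)
    raw_path = out / "parameters_raw.csv"
    raw.to_csv(raw_path, index=False, float_format="%.12g")
    report = raw[REPORT_COLUMNS].copy()
    for col in ("D", "C", "L", "H"):
        report[col] = report[col].map(lambda v: f"{round_half_away(v, 3):.3f}")
    report_path = out / "parameters.csv"
    report.to_csv(report_path, index=False)
    written["parameters.csv"] = str(report_path)
    written["parameters_raw.csv"] = str(raw_path)

    if cfg.tree is not None:
        try:
            tree = read_newick(cfg.tree)
            sig_rows = []
            rng_base = int(cfg.seed) % (2**31 - 1)
            for i, trait in enumerate(cfg.traits):
                vals = dict(zip(raw["Taxa"], raw[trait].astype(float)))
                lam = fit_pagel_lambda(vals, tree)
                kres = blomberg_k(vals, tree, n_perm=cfg.n_permutations,
                                  seed=(rng_base + 7919 * i) % (2**31 - 1))
                sig_rows.append({
                    "trait": trait,
                    "lambda": lam.estimate, "p_lambda": lam.p_value,
                    "K": kres.estimate, "p_K": kres.p_value,
                })
                anc = ancestral_states(vals, tree, trait=trait)
                ppath = out / f"phenogram_{trait}.csv"
                phenogram_export(anc, ppath)
                written[f"phenogram_{trait}.csv"] = str(ppath)
                log.info("stage=phylosig trait=%s lambda=%.3f K=%.3f",
                         trait, lam.estimate, kres.estimate)
        except Exception as exc:
            raise RuntimeError(f"stage 'phylo' failed on input {cfg.tree!r}: {exc}") from exc
        sig_path = out / "phylosig.csv"
        pd.DataFrame(sig_rows).to_csv(sig_path, index=False, float_format="%.12g")
        written["phylosig.csv"] = str(sig_path)

    manifest = {
        "config": asdict(cfg),
        "version": __version__,
        "inputs": {p: _file_hash(p) for p in cfg.networks},
        "outputs": sorted(written),
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    written["manifest.json"] = str(mpath)
    return written


# ---------------------------------------------------------------------------
# validation against a published reference table
# ---------------------------------------------------------------------------

def validate_against_reference(
    params: pd.DataFrame,
    reference: pd.DataFrame,
    taxon_column: str = "Taxa",
    reference_taxon_column: str = "taxon",
) -> dict:
    """Compare computed per-taxon parameters with a published table.

    For users re-running the pipeline on the original dissection-derived
    adjacency matrices: node and link counts must match the published
    N and K exactly (they are raw counts), while the module count M is
    compared as a range — walktrap tie-breaking may legitimately differ
    between implementations, so per-taxon M equality is reported but
    not required.

    Returns a dict with ``nk_mismatches`` (list of (taxon, field,
    computed, published)), ``m_range`` and ``reference_m_range``
    ((min, max) tuples), ``m_matches`` (count of taxa with equal M) and
    ``n_taxa_compared``.
    """
    from .phylo import normalize_taxon

    ref = {normalize_taxon(t): row
           for t, row in zip(reference[reference_taxon_column],
                             reference.to_dict("records"))}
    mismatches = []
    m_comp, m_ref, m_eq = [], [], 0
    compared = 0
    for row in params.to_dict("records"):
        key = normalize_taxon(str(row[taxon_column]))
        if key not in ref:
            continue
        compared += 1
        for fieldname in ("N", "K"):
            if int(row[fieldname]) != int(ref[key][fieldname]):
                mismatches.append(
                    (row[taxon_column], fieldname,
                     int(row[fieldname]), int(ref[key][fieldname]))
                )
        if "M" in row and not pd.isna(row["M"]):
            m_comp.append(int(row["M"]))
            m_ref.append(int(ref[key]["M"]))
            m_eq += int(row["M"]) == int(ref[key]["M"])
    return {
        "n_taxa_compared": compared,
        "nk_mismatches": mismatches,
        "m_range": (min(m_comp), max(m_comp)) if m_comp else None,
        "reference_m_range": (min(m_ref), max(m_ref)) if m_ref else None,
        "m_matches": m_eq,
    }


# ---------------------------------------------------------------------------
# group summaries
# ---------------------------------------------------------------------------

def quartile_band(value: float, sample: pd.Series | np.ndarray) -> str:
    """Place a value among a sample's quartile bands.

    Bands are ``below-q1``, ``q1-q2``, ``q2-q3`` and ``above-q3``
    (quartiles by linear interpolation, the inclusive convention).
    Values equal to a quartile boundary fall in the lower band.
    """
    q1, q2, q3 = np.quantile(np.asarray(sample, dtype=float), [0.25, 0.5, 0.75])
    if value <= q1:
        return "below-q1"
    if value <= q2:
        return "q1-q2"
    if value <= q3:
        return "q2-q3"
    return "above-q3"


def summarize_group(
    params: pd.DataFrame,
    groups: dict[str, str],
    columns: list[str] | None = None,
    taxon_column: str = "Taxa",
) -> pd.DataFrame:
    """Per-group mean, sd and quartiles of each parameter column.

    ``groups`` maps every taxon in ``params`` to a group label; an
    unmapped taxon is an error.  Single-taxon groups report their value
    as the mean and a missing (NaN) sd.  Returns a tidy frame with one
    row per (group, parameter).
    """
    taxa = params[taxon_column]
    missing = [t for t in taxa if t not in groups]
    if missing:
        raise ValueError(f"taxa missing from group map: {missing[:5]}")
    if columns is None:
        columns = [c for c in params.columns
                   if c != taxon_column and pd.api.types.is_numeric_dtype(params[c])]

    rows = []
    for group in sorted(set(groups[t] for t in taxa)):
        sel = params[[groups[t] == group for t in taxa]]
        for col in columns:
            vals = sel[col].astype(float)
            q1, q2, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
            rows.append({
                "group": group,
                "parameter": col,
                "n": len(vals),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                "q1": float(q1),
                "median": float(q2),
                "q3": float(q3),
            })
    return pd.DataFrame(rows)
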