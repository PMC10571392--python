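"""End-to-end orchestration with a reproducible run manifest.

Stages run in dependency order (simulate/ingest -> catalog -> signatures ->
funcconfig -> ordinate -> toxins -> classify).  The manifest records the
configuration hash, the master seed, package versions and a SHA-256 checksum
of every stage output, so an identical configuration reproduces identical
checksums for all deterministic stages.  All stage randomness derives from
one master seed through named substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog import ValidationError, dereplicate, filter_catalog
from .classify import ckd_generalization, cross_cohort_classify, train_evaluate
from .community import bray_curtis, pcoa, permanova
from .signatures import discover_signatures
from .simulate import SimulationConfig, simulate_all
from .toxins import ToxinExplainer, default_k_grid, standardize_toxin

log = logging.getLogger("metasig")

STAGES = ("simulate", "catalog", "signatures", "funcconfig", "ordinate",
          "toxins", "classify")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(master_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _flatten(obj, prefix=""):
    """(path, value) pairs for hashing arbitrarily nested configs."""
    if isinstance(obj, dict):
        for k, v in obj.items():
            yield from _flatten(v, f"{prefix}/{k}")
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            yield from _flatten(v, f"{prefix}[{i}]")
    else:
        yield (prefix, repr(obj))


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if "seed" not in cfg:
        raise ValidationError("config must set a master seed")
    return cfg


def validate_inputs(abundance: pd.DataFrame, metadata: pd.DataFrame) -> list:
    """Collect every violation of the basic table contracts (not just the first)."""
    violations = []
    missing = set(abundance.index) - set(metadata.index)
    if missing:
        violations.append(
            f"samples in abundance but not metadata: {sorted(missing)[:10]}"
        )
    if (abundance.values < 0).any():
        bad = abundance.index[(abundance.values < 0).any(axis=1)]
        violations.append(f"negative abundances in samples {list(bad)[:10]}")
    rowsums = abundance.sum(axis=1)
    over = abundance.index[rowsums > 1 + 1e-9]
    if len(over):
        violations.append(f"row sums exceed 1: {list(over)[:10]}")
    for col in ("cohort", "group"):
        if col in metadata.columns and metadata[col].isna().any():
            violations.append(f"metadata column {col!r} has missing values")
    return violations


def run_pipeline(config: dict, out_dir) -> dict:
    """Run all enabled stages; return the manifest (also written to disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master_seed = int(config["seed"])
    enabled = config.get("stages", list(STAGES))
    thresholds = config.get("thresholds", {})
    manifest = {
        "version": __version__,
        "seed": master_seed,
        "config_hash": hashlib.sha256(
            repr(sorted(_flatten(config))).encode()
        ).hexdigest(),
        "stages": {},
    }

    def record(stage, paths, started):
        manifest["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in paths},
            "seconds": round(time.time() - started, 3),
            "seed": _stage_seed(master_seed, stage),
        }

    data = None
    try:
        if "simulate" in enabled:
            t0 = time.time()
            sim_cfg = SimulationConfig(
                seed=_stage_seed(master_seed, "simulate"),
                **config.get("simulate", {}),
            )
            log.info("simulate: n_species=%d arms=%s", sim_cfg.n_species,
                     dict(sim_cfg.n_per_arm))
            data = simulate_all(sim_cfg)
            data["abundance"].to_csv(out / "abundance.tsv", sep="\t")
            data["metadata"].to_csv(out / "metadata.tsv", sep="\t", index=False)
            data["toxins"].to_csv(out / "toxins.tsv", sep="\t")
            data["ko_presence"].to_csv(out / "ko_presence.tsv", sep="\t")
            data["identity"].to_csv(out / "identity.tsv", sep="\t")
            from .catalog import write_mags_tsv

            write_mags_tsv(data["bins"], out / "mags.tsv")
            data["truth"].to_json(out / "truth.json")
            record("simulate", sorted(out.glob("*.tsv")) + [out / "truth.json"], t0)
        else:
            from .io import read_abundance, read_metadata

            paths = config["inputs"]
            data = {
                "abundance": read_abundance(paths["abundance"]),
                "metadata": read_metadata(paths["metadata"]),
            }

        violations = validate_inputs(data["abundance"], data["metadata"])
        if violations:
            raise ValidationError("input validation failed: " + "; ".join(violations))

        if "catalog" in enabled and "bins" in data:
            t0 = time.time()
            retained = filter_catalog(data["bins"])
            clusters = dereplicate(
                retained, data["identity"],
                threshold=thresholds.get("derep_identity", 0.95),
            )
            log.info("catalog: %d bins -> %d retained -> %d clusters "
                     "(identity > %.2f)", len(data["bins"]), len(retained),
                     len(clusters), thresholds.get("derep_identity", 0.95))
            from .catalog import clusters_to_frame

            clusters_to_frame(clusters).to_csv(out / "clusters.tsv", sep="\t",
                                               index=False)
            record("catalog", [out / "clusters.tsv"], t0)

        signatures = None
        if "signatures" in enabled:
            t0 = time.time()
            signatures = discover_signatures(
                data["abundance"], data["metadata"],
                fdr_method=thresholds.get("fdr_method", "bh"),
                fc_threshold=thresholds.get("fc_threshold", 1.2),
                q_threshold=thresholds.get("q_threshold", 0.2),
                combined_q_threshold=thresholds.get("combined_q_threshold", 0.05),
            )
            log.info("signatures: q<%.2f fc>%.2f combined q<%.2f -> %d calls",
                     thresholds.get("q_threshold", 0.2),
                     thresholds.get("fc_threshold", 1.2),
                     thresholds.get("combined_q_threshold", 0.05),
                     int((signatures["call"] != "none").sum()))
            signatures.to_csv(out / "signatures.tsv", sep="\t")
            record("signatures", [out / "signatures.tsv"], t0)

        if "funcconfig" in enabled and "ko_presence" in data and signatures is not None:
            t0 = time.time()
            from .functions import occurrence_contrast

            called = signatures[signatures["call"] != "none"]["call"]
            called = called[called.index.isin(data["ko_presence"].index)]
            if called.nunique() == 2:
                contrast = occurrence_contrast(
                    data["ko_presence"].loc[called.index], called
                )
                contrast.to_csv(out / "ko_contrasts.tsv", sep="\t")
                record("funcconfig", [out / "ko_contrasts.tsv"], t0)
            else:
                log.info("funcconfig skipped: need both enrichment directions")

        if "ordinate" in enabled:
            t0 = time.time()
            dist = bray_curtis(data["abundance"])
            ord_res = pcoa(dist)
            factors = [
                f for f in config.get("factors", ["group", "cohort"])
                if f in data["metadata"].columns
            ]
            perm = permanova(
                dist, data["metadata"].loc[dist.index, factors],
                n_perm=int(thresholds.get("n_perm", 1000)),
                seed=_stage_seed(master_seed, "ordinate"),
            )
            dist.to_csv(out / "distances.tsv", sep="\t")
            ord_res.coordinates.to_csv(out / "pcoa_coords.tsv", sep="\t")
            pd.DataFrame(
                {"eigenvalue": ord_res.eigenvalues,
                 "variance_explained": ord_res.variance_explained}
            ).to_csv(out / "eigen.tsv", sep="\t", index=False)
            pd.DataFrame([vars(r) for r in perm]).to_csv(
                out / "permanova.tsv", sep="\t", index=False
            )
            record("ordinate", [out / "distances.tsv", out / "pcoa_coords.tsv",
                                out / "eigen.tsv", out / "permanova.tsv"], t0)

        if "toxins" in enabled and "toxins" in data:
            t0 = time.time()
            tox_cfg = config.get("toxins", {})
            rows = {}
            cases = data["metadata"].index[data["metadata"]["group"] != "HC"]
            for toxin in data["toxins"].columns:
                y = standardize_toxin(
                    data["toxins"].loc[cases, toxin],
                    data["metadata"].loc[cases, "cohort"],
                )
                model = ToxinExplainer(
                    n_estimators=int(tox_cfg.get("n_estimators", 500)),
                    random_state=_stage_seed(master_seed, f"toxins:{toxin}"),
                    k_grid=tox_cfg.get(
                        "k_grid", default_k_grid(data["abundance"].shape[1])
                    ),
                ).fit(data["abundance"].loc[cases], y)
                rows[toxin] = {
                    "r2_full": model.r2_full_,
                    "best_k": model.best_k_,
                    "r2_best": model.r2_best_,
                    "selected_species": ",".join(model.selected_species_),
                }
            pd.DataFrame(rows).T.to_csv(out / "toxin_models.tsv", sep="\t")
            record("toxins", [out / "toxin_models.tsv"], t0)

        if "classify" in enabled:
            t0 = time.time()
            meta = data["metadata"]
            labels = (meta["group"] != "HC").astype(int)
            results = {}
            res = train_evaluate(
                data["abundance"], labels,
                seed=_stage_seed(master_seed, "classify"),
                n_estimators=int(config.get("classify", {}).get("n_estimators", 500)),
            )
            results["within"] = {"auc": res.auc, "ci95": list(res.ci95)}
            cohorts = sorted(meta["cohort"].unique())
            if len(cohorts) == 2:
                a = meta.index[meta["cohort"] == cohorts[0]]
                b = meta.index[meta["cohort"] == cohorts[1]]
                res = cross_cohort_classify(
                    data["abundance"].loc[a], labels.loc[a],
                    data["abundance"].loc[b], labels.loc[b],
                    seed=_stage_seed(master_seed, "classify"),
                )
                results["cross_cohort"] = {"auc": res.auc, "ci95": list(res.ci95)}
            if {"CKD3_4", "CKD5N"} <= set(meta["group"]):
                ckd = ckd_generalization(
                    data["abundance"], meta,
                    seed=_stage_seed(master_seed, "classify"),
                )
                for g, r in ckd.items():
                    results[f"ckd_{g}"] = {"auc": r.auc, "ci95": list(r.ci95)}
            (out / "classification.json").write_text(json.dumps(results, indent=2))
            record("classify", [out / "classification.json"], t0)
    except Exception as exc:
        manifest["failed_stage"] = getattr(exc, "stage", "unknown")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
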