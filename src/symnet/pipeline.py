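"""End-to-end analysis pipeline.

Reads one observation table, builds the three community matrices
(parasitoid, plant, symbiont strain), converts them to similarity
matrices, screens diversity relationships, fits the two matrix-regression
models (strain similarity ~ parasitoid similarity + relatedness, and
strain ~ plant + relatedness, each on its own aligned species set),
scores specialisation of the three bipartite networks against the
fixed-marginal null, projects strains onto parasitoids, and summarises
pairwise sharing.  Every result file embeds the config hash and seeds, so
a rerun with the same config and inputs is byte-identical apart from
nothing (no timestamps are written).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import distances, diversity, network
from .mmrr import mmrr as mmrr_fit
from .observations import (
    CommunityMatrix,
    FilterConfig,
    ObservationTable,
    align_species,
    build_community_matrix,
    filter_observations,
    read_observations,
)
from .otu import SequenceSet


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on, in one declarative object."""

    observations: str | None = None
    sequences: str | None = None  # aligned marker FASTA, one id per species
    out_dir: str = "symnet_out"
    column_map: dict[str, str] = field(default_factory=dict)
    host_list: dict[str, list[str]] | None = None
    drop_transient: bool = True
    normalize: bool = False
    rarefaction_depth: int = 7
    rarefaction_reps: int = 1000
    mmrr_nperm: int = 9999
    h2_n_null: int = 1000
    relatedness_mode: str = "raw_distance"
    pair_threshold: float = 0.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _log(msg: str, lines: list[str]) -> None:
    lines.append(msg)
    print(msg, file=sys.stderr)


def run_pipeline(
    config: PipelineConfig,
    table: ObservationTable | None = None,
    seqs: SequenceSet | None = None,
) -> dict:
    """Run every stage and write the result bundle to ``config.out_dir``.

    ``table``/``seqs`` may be passed directly (e.g., from the synthetic
    generator) instead of reading ``config.observations``/``config.sequences``.
    Returns a dict of in-memory results keyed by artefact name.
    """
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    meta = {"config_hash": cfg.hash(), "seed": cfg.seed}

    if table is None:
        if cfg.observations is None:
            raise ValueError("no observation table provided")
        table = read_observations(cfg.observations, column_map=cfg.column_map or None)
    if seqs is None and cfg.sequences is not None:
        seqs = SequenceSet.from_fasta(cfg.sequences)
    _log(f"[read] {len(table)} observation records", log)

    # stage: filter + community matrices
    matrices: dict[str, CommunityMatrix] = {}
    for kind in ("parasitoid", "plant", "strain"):
        try:
            filt = filter_observations(
                table,
                FilterConfig(
                    partner_kind=kind,
                    host_list=cfg.host_list,
                    drop_transient=cfg.drop_transient,
                ),
            )
            matrices[kind] = build_community_matrix(filt, kind)
        except Exception as exc:
            raise RuntimeError(f"[matrices:{kind}] {exc}") from exc
        matrices[kind].to_csv(out / f"matrix_{kind}.csv")
        _log(
            f"[matrices] {kind}: {len(matrices[kind].focal_labels)} species x "
            f"{len(matrices[kind].partner_labels)} taxa",
            log,
        )

    # stage: relatedness
    relatedness = None
    if seqs is not None:
        reps = {sp: sp for sp in matrices["strain"].focal_labels if sp in seqs.ids}
        D = distances.gene_distance_matrix(seqs, reps)
        relatedness = distances.relatedness_transform(D, cfg.relatedness_mode)
        relatedness.to_csv(out / "relatedness.csv")
        _log(f"[relatedness] mode={cfg.relatedness_mode}, {len(D)} species", log)

    # stage: diversity screen
    rng = np.random.default_rng(cfg.seed)
    div = diversity.diversity_table(
        matrices,
        depth=cfg.rarefaction_depth,
        reps=cfg.rarefaction_reps,
        seed=int(rng.integers(2**31)),
    )
    div.to_csv(out / "diversity.csv", index=False)
    screens = {}
    full = div[div.variant == "full"].pivot_table(
        index="species", columns="partner_kind", values="shannon"
    )
    for pred in ("parasitoid", "plant"):
        sub = full[[pred, "strain"]].dropna()
        if len(sub) >= 3 and sub[pred].nunique() > 1:
            fit = diversity.fit_diversity_model(sub[pred], sub["strain"])
            screens[f"strain_shannon_vs_{pred}"] = dataclasses.asdict(fit)
    (out / "diversity_models.json").write_text(
        json.dumps({**meta, "models": screens}, indent=2) + "\n"
    )

    # stage: similarity + the two MMRR models
    results: dict = {"matrices": matrices, "diversity": div, "screens": screens}
    for model, partner in (("parasitoid_model", "parasitoid"), ("plant_model", "plant")):
        try:
            aligned, rel, dropped = align_species(
                [matrices["strain"], matrices[partner]], relatedness
            )
        except Exception as exc:
            raise RuntimeError(f"[align:{model}] {exc}") from exc
        if dropped:
            _log(f"[align:{model}] dropped species: {dropped}", log)
        sim_strain = distances.community_similarity(aligned[0], cfg.normalize)
        sim_partner = distances.community_similarity(aligned[1], cfg.normalize)
        sim_strain.to_csv(out / f"similarity_strain_{model}.csv")
        sim_partner.to_csv(out / f"similarity_{partner}.csv")
        Xs, names = [sim_partner], [partner]
        if rel is not None:
            Xs.append(rel)
            names.append(f"relatedness_{cfg.relatedness_mode}")
        res = mmrr_fit(
            sim_strain, Xs, names=names, nperm=cfg.mmrr_nperm,
            seed=int(rng.integers(2**31)),
        )
        res.provenance = {**meta, "model": model, "dropped_species": dropped}
        res.to_json(out / f"mmrr_{model}.json")
        results[f"mmrr_{model}"] = res
        _log(
            f"[mmrr:{model}] n={res.n_species} beta=" +
            ", ".join(f"{nm}={b:.4f} (p={p:.4f})" for nm, b, p in
                      zip(res.predictor_names, res.beta, res.p_perm)),
            log,
        )

        summary = network.shared_pair_summary(
            sim_strain, sim_partner, threshold=cfg.pair_threshold,
            strain_matrix=aligned[0],
        )
        summary.to_csv(out / f"pairs_{model}.csv")
        results[f"pairs_{model}"] = summary
        _log(
            f"[pairs:{model}] {summary.n_strain_sharing} strain-sharing pairs; "
            f"{summary.n_strain_and_partner_sharing} "
            f"({summary.pct_partner_among_strain_sharing:.1f}%) also share {partner}s",
            log,
        )

    # stage: specialisation of the three bipartite networks
    h2_inputs = {
        "aphid_parasitoid": matrices["parasitoid"].counts,
        "aphid_strain": matrices["strain"].counts,
    }
    proj, proj_dropped = network.project_parasitoid_symbiont(
        matrices["parasitoid"], matrices["strain"]
    )
    network.write_edge_list(proj, out / "projection_parasitoid_strain.csv")
    if proj_dropped:
        _log(f"[project] dropped aphids: {proj_dropped}", log)
    projR = proj.round().astype(int)
    projR = projR.loc[projR.sum(axis=1) > 0, projR.sum(axis=0) > 0]
    h2_inputs["parasitoid_strain"] = projR
    h2_results = {}
    for name, counts in h2_inputs.items():
        res = network.h2_ses(
            counts, n_null=cfg.h2_n_null, seed=int(rng.integers(2**31))
        )
        h2_results[name] = res
        _log(f"[h2:{name}] H2'={res.h2prime:.3f} SES={res.ses:.1f}", log)
    (out / "h2_ses.json").write_text(
        json.dumps(
            {**meta, **{k: dataclasses.asdict(v) for k, v in h2_results.items()}},
            indent=2,
        )
        + "\n"
    )
    results["h2"] = h2_results
    results["projection"] = proj

    (out / "run_log.txt").write_text("\n".join(table.provenance + log) + "\n")
    return results
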