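"""File-mediated pipeline: simulate -> align -> conserve -> features ->
clusters -> cost -> associate -> report.

Every stage reads and writes declared files under the configured output
directory, so stages can be re-run independently and never mutate each
other's outputs. Each output TSV carries the configuration hash and the
master seed in a header comment; a re-run with the same configuration and
seed is bit-identical.
"""
from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .align import AlignParams, refine_orthogroups, tm_matrix
from .conservation import profile_tables
from .exceptions import ConfigError, UndefinedStatisticError
from .io import Orthogroup, read_structure, write_manifest, write_pdb
from .model import ConservationAnalysis, FitParams
from .synthetic import SyntheticSpec, generate_corpus, generate_property_tables

STAGES = ("simulate", "align", "conserve", "features", "clusters", "cost",
          "associate", "report")


@dataclass
class PipelineConfig:
    output_dir: str = "pipeline_out"
    structures_dir: str | None = None   # defaults to <output_dir>/structures
    manifest: str | None = None
    properties: str | None = None
    annotations: str | None = None
    seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGES))
    # simulation preset
    simulate: dict = field(default_factory=dict)   # SyntheticSpec overrides
    # analysis parameters
    prune_cutoff: float = 2.0
    map_cutoff: float = 5.0
    linkage_cutoff: float = 0.2
    quorum: float = 1.0
    surface_threshold: float = 0.25
    csb_cutoff: float = 5.0
    contact_cutoff: float = 10.0
    min_cluster_size: int = 3
    refine: bool = False  # recluster each orthogroup by bidirectional TM

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for st in cfg.stages:
            if st not in STAGES:
                raise ConfigError(f"unknown stage: {st}")
        if not (0 < cfg.quorum <= 1):
            raise ConfigError("quorum must be in (0, 1]")
        return cfg

    def hash(self) -> str:
        """Hash of the analysis parameters (paths excluded, so the same
        configuration in a different directory hashes identically)."""
        d = asdict(self)
        for key in ("output_dir", "structures_dir", "manifest", "properties",
                    "annotations"):
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)

    def paths(self) -> dict:
        out = Path(self.output_dir)
        return {
            "out": out,
            "structures": Path(self.structures_dir) if self.structures_dir
            else out / "structures",
            "manifest": Path(self.manifest) if self.manifest else out / "manifest.tsv",
            "properties": Path(self.properties) if self.properties
            else out / "properties.tsv",
            "mappings": out / "mappings.tsv",
            "align_summary": out / "align_summary.tsv",
            "og_summary": out / "og_summary.tsv",
            "residue_profile": out / "residue_profile.tsv",
            "features": out / "features.tsv",
            "clusters": out / "clusters.tsv",
            "cluster_summary": out / "cluster_summary.tsv",
            "overlap": out / "overlap.tsv",
            "cost_report": out / "cost_report.tsv",
            "associations": out / "associations.tsv",
            "summary": out / "summary.json",
        }


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# structcons config={cfg.hash()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def stage_simulate(cfg: PipelineConfig) -> None:
    spec = SyntheticSpec(seed=cfg.stage_seed("simulate"), **cfg.simulate)
    ogs, truths = generate_corpus(spec)
    props = generate_property_tables(truths, spec)
    paths = cfg.paths()
    sdir = paths["structures"]
    sdir.mkdir(parents=True, exist_ok=True)
    models, og_of = [], {}
    for og in ogs.values():
        for mid in og.member_ids:
            m = og.structure(mid)
            write_pdb(m, sdir / f"{mid}.pdb")
            models.append(m)
            og_of[mid] = og.og_id
    write_manifest(models, og_of, paths["manifest"])
    props.reset_index().to_csv(paths["properties"], sep="\t", index=False)
    truth_out = {og_id: {"pocket": t.pocket, "cr_true": t.cr_true,
                         "classes": list(t.classes)}
                 for og_id, t in truths.items()}
    with open(paths["out"] / "truth.json", "w") as fh:
        json.dump(truth_out, fh, indent=1)


def load_corpus(cfg: PipelineConfig) -> list[Orthogroup]:
    paths = cfg.paths()
    man = pd.read_csv(paths["manifest"], sep="\t")
    ogs = []
    for og_id, sub in man.groupby("og_id"):
        mids = sorted(sub["structure_id"])
        structures = {mid: read_structure(paths["structures"] / f"{mid}.pdb",
                                          plddt_from_bfactor=True,
                                          structure_id=mid)
                      for mid in mids}
        refs = [m for m in mids if m.startswith("ref")] or [mids[0]]
        ogs.append(Orthogroup(og_id, mids, refs[:1], structures))
    return ogs


def _fit_params(cfg: PipelineConfig) -> FitParams:
    return FitParams(
        align=AlignParams(prune_cutoff=cfg.prune_cutoff, map_cutoff=cfg.map_cutoff),
        quorum=cfg.quorum, surface_threshold=cfg.surface_threshold,
        csb_cutoff=cfg.csb_cutoff, contact_cutoff=cfg.contact_cutoff,
        min_cluster_size=cfg.min_cluster_size)


def _fit(cfg: PipelineConfig):
    annotations = None
    if cfg.annotations:
        annotations = pd.read_csv(cfg.annotations, sep="\t")
    model = ConservationAnalysis(load_corpus(cfg), annotations=annotations,
                                 params=_fit_params(cfg))
    return model.fit()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured stages in order; returns the report dictionary.

    The heavy lifting is fitted once and stage outputs are serialized from
    the shared results object, so all cross-stage flow is reproducible from
    the declared files.
    """
    paths = cfg.paths()
    paths["out"].mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGES if s in cfg.stages]
    if "simulate" in stages:
        stage_simulate(cfg)
    need_fit = any(s in stages for s in
                   ("align", "conserve", "features", "clusters", "cost"))
    res = _fit(cfg) if need_fit else None

    if "align" in stages:
        rows, arows = [], []
        for og_id, al in sorted(res.alignments.items()):
            for mid, a in sorted(al.items()):
                ref_seq = res.profiles[og_id].ref_sequence
                mem_seq = res.model.orthogroups[og_id].structure(mid).sequence
                for r_idx, m_idx in a.mapping.pairs:
                    rows.append((og_id, mid, r_idx, m_idx,
                                 ref_seq[r_idx - 1], mem_seq[m_idx - 1]))
                arows.append({"og_id": og_id, "member_id": mid,
                              "tm_ref": a.tm_ref, "tm_mem": a.tm_mem,
                              "tm_bidir": a.tm_bidir,
                              "rmsd": a.superposition.rmsd,
                              "n_mapped": len(a.mapping)})
        _write_tsv(pd.DataFrame(rows, columns=["og_id", "member_id", "ref_idx",
                                               "mem_idx", "ref_aa", "mem_aa"]),
                   paths["mappings"], cfg)
        _write_tsv(pd.DataFrame(arows), paths["align_summary"], cfg)
        if cfg.refine:
            rrows = []
            for og_id, og in sorted(res.model.orthogroups.items()):
                members = [og.structure(m) for m in sorted(og.member_ids)]
                tm = tm_matrix(members, _fit_params(cfg).align)
                groups = refine_orthogroups(list(tm.index), tm.to_numpy(),
                                            cfg.linkage_cutoff)
                for k, grp in enumerate(groups):
                    for sid in grp:
                        rrows.append({"og_id": og_id,
                                      "refined_og": f"{og_id}.{k}",
                                      "structure_id": sid})
            _write_tsv(pd.DataFrame(rrows), paths["out"] / "refined_orthogroups.tsv",
                       cfg)

    if "conserve" in stages:
        summaries, residues = [], []
        for og_id, prof in sorted(res.profiles.items()):
            s, r = profile_tables(prof)
            summaries.append(s)
            residues.append(r)
        _write_tsv(res.orthogroup_table, paths["og_summary"], cfg)
        _write_tsv(pd.concat(residues, ignore_index=True),
                   paths["residue_profile"], cfg)

    if "features" in stages:
        frames = []
        for og_id, feat in sorted(res.features.items()):
            f = feat.copy()
            f.insert(0, "og_id", og_id)
            frames.append(f)
        _write_tsv(pd.concat(frames, ignore_index=True), paths["features"], cfg)

    if "clusters" in stages:
        rows = []
        for og_id, cs in sorted(res.cluster_sets.items()):
            for cid, members in enumerate(cs.clusters):
                rows.append({"og_id": og_id, "cluster_id": cid,
                             "size": len(members),
                             "residues": ",".join(map(str, members))})
        _write_tsv(pd.DataFrame(rows), paths["clusters"], cfg)
        _write_tsv(res.cluster_stats(), paths["cluster_summary"], cfg)
        _write_tsv(res.cluster_overlap("csb"), paths["overlap"], cfg)

    if "cost" in stages:
        _write_tsv(res.element_costs(), paths["cost_report"], cfg)

    if "associate" in stages:
        props_path = paths["properties"]
        if props_path.exists():
            props = pd.read_csv(props_path, sep="\t").set_index("og_id")
            og_tab = _read_tsv(paths["og_summary"])
            assoc = _associate_from_tables(og_tab, props)
            _write_tsv(assoc, paths["associations"], cfg)

    report = {"config_hash": cfg.hash(), "seed": cfg.seed, "stages": stages,
              "effective_config": asdict(cfg)}
    if "report" in stages:
        for name in ("og_summary", "cluster_summary", "associations"):
            p = paths[name]
            if p.exists():
                try:
                    df = _read_tsv(p)
                except pd.errors.EmptyDataError:
                    df = pd.DataFrame()
                report[f"n_rows_{name}"] = int(len(df))
        if paths["og_summary"].exists():
            tab = _read_tsv(paths["og_summary"])
            report["median_mr"] = float(tab["og_mr"].median())
            report["median_cr"] = float(tab["og_cr"].median())
        report["checksums"] = {
            name: hashlib.sha256(paths[name].read_bytes()).hexdigest()[:16]
            for name in ("mappings", "og_summary", "residue_profile", "features",
                         "clusters", "cost_report")
            if paths[name].exists()}
        with open(paths["summary"], "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
    return report


def _associate_from_tables(og_tab: pd.DataFrame, props: pd.DataFrame) -> pd.DataFrame:
    from . import stats as st

    joined = og_tab.set_index("og_id").join(props, how="inner")
    results = []
    for col in props.columns:
        if not pd.api.types.is_numeric_dtype(props[col]):
            continue
        method = "kendall" if col in ("flux_n_species", "n_inhibitors",
                                      "ppi_degree") else "spearman"
        try:
            r = st.correlate(joined["og_cr"], joined[col], method)
        except UndefinedStatisticError:
            continue
        r.meta["variable"] = col
        results.append(r)
    return st.association_report(results)
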