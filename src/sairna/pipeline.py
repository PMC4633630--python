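"""Configuration and end-to-end pipeline orchestration.

A :class:`RunConfig` (usually loaded from YAML) fully determines every
output: design parameters, cassette options, processing options and the
off-target stage.  Each run writes the resolved configuration next to
its outputs and stamps every TSV artifact with the tool version and a
hash of the configuration, so identical configs reproduce byte-identical
results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .designer import (
    DesignConstraints,
    DesignError,
    build_hairpin,
    build_shrna_classic,
    make_cloning_oligos,
    rank_candidates,
    scan_target_sites,
)
from .offtarget import attribute_deg, major_isoform_seed, scan_seed_matches
from .processing import SimOptions, simulate
from .seqcore import read_fasta

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    # inputs
    target_fasta: str = ""
    utr_fasta: str | None = None
    expression_tsv: str | None = None
    # design
    mode: str = "sairna"  # sairna | shrna | shrna_classic
    stem_len: int = 17
    loop_len: int = 4
    mismatch_base: str = "C"
    gc_min: float = 0.25
    gc_max: float = 0.75
    max_homopolymer: int = 3
    top_n: int = 5
    vector: str = "H1_pSilencer"
    # cassette / simulation
    promoter: str = "H1"
    ribozyme: str = "WT"
    spacer: str = "UU"
    terminator_len: int = 6
    # off-target
    fpkm_min: float = 10.0
    fold_change: float = 1.5
    # misc
    seed: int = 0
    out_dir: str = "sairna_out"
    stages: tuple[str, ...] = ("design", "simulate", "offtarget")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d

    def hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _header(cfg: RunConfig) -> str:
    return f"# sairna v{__version__} config={cfg.hash()}\n"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute the configured stages in order; returns artifact paths.

    Stage failures raise :class:`PipelineError` naming the stage.  Later
    stages are skipped when not configured.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    artifacts: dict[str, Path] = {"config": out / "resolved_config.yaml"}

    if not Path(cfg.target_fasta).exists():
        raise PipelineError(f"design: target FASTA not found: {cfg.target_fasta}")
    targets = read_fasta(cfg.target_fasta, alphabet="RNA")

    # ---- design ----------------------------------------------------------
    designs = []
    try:
        constraints = DesignConstraints(
            stem_len=cfg.stem_len,
            loop_len=cfg.loop_len,
            mismatch_base=cfg.mismatch_base,
            gc_min=cfg.gc_min,
            gc_max=cfg.gc_max,
            max_homopolymer=cfg.max_homopolymer,
        )
        rows = []
        for rec in targets:
            sites = scan_target_sites(rec, constraints)
            for site in sites:
                if cfg.mode == "shrna_classic":
                    d = build_shrna_classic(site, stem_len=cfg.stem_len)
                else:
                    d = build_hairpin(
                        site, cfg.stem_len, cfg.loop_len, cfg.mismatch_base
                    )
                designs.append(d)
        ranked = rank_candidates(designs)[: cfg.top_n] if designs else []
        designs = [r.design for r in ranked]
        for r in ranked:
            d = r.design
            try:
                pair = make_cloning_oligos(d, cfg.vector, cfg.terminator_len)
                top, bottom = pair.top.residues, pair.bottom.residues
            except DesignError as err:  # uncloneable in this vector; keep the design
                logger.warning(
                    "design at %s:%d not cloneable: %s", d.site.source_id, d.site.start, err
                )
                top = bottom = "NA"
            rows.append(
                {
                    "target": d.site.source_id,
                    "start": d.site.start,
                    "window": d.site.window.residues,
                    "guide": d.guide.residues,
                    "hairpin": d.core.residues,
                    "score": round(r.total, 4),
                    "asymmetry": round(r.subscores["asymmetry"], 4),
                    "gc": round(d.site.gc, 3),
                    "oligo_top": top,
                    "oligo_bottom": bottom,
                }
            )
        _write_tsv(pd.DataFrame(rows), out / "designs.tsv", cfg)
        artifacts["designs"] = out / "designs.tsv"
    except Exception as e:  # noqa: BLE001 - stage-named re-raise
        raise PipelineError(f"design: {e}") from e
    if "simulate" not in cfg.stages or not designs:
        return artifacts

    # ---- simulate --------------------------------------------------------
    try:
        opts = SimOptions(
            promoter=cfg.promoter,
            ribozyme=cfg.ribozyme,
            spacer=cfg.spacer,
            terminator_len=cfg.terminator_len,
        )
        outcomes = [simulate(d, opts) for d in designs]
        payload = []
        for o in outcomes:
            payload.append(
                {
                    "target": o.design.site.source_id if o.design.site else "",
                    "start": o.design.site.start if o.design.site else 0,
                    "category": o.category.value,
                    "overhang3": o.loading.overhang3,
                    "ago2_load": o.loading.ago2_load_weight,
                    "species": [
                        {"name": s.name, "seq": s.seq.residues, "weight": round(s.weight, 6)}
                        for s in o.species
                    ],
                    "ago_table": o.ago_table.round(6).to_dict(),
                }
            )
        with open(out / "outcomes.json", "w") as fh:
            json.dump(
                {"version": __version__, "config": cfg.hash(), "outcomes": payload},
                fh,
                indent=2,
            )
        artifacts["outcomes"] = out / "outcomes.json"
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"simulate: {e}") from e
    if "offtarget" not in cfg.stages or cfg.utr_fasta is None:
        return artifacts

    # ---- offtarget -------------------------------------------------------
    try:
        utrs = read_fasta(cfg.utr_fasta, alphabet="RNA")
        rows = []
        for o in outcomes:
            gseed = major_isoform_seed(o, "GUIDE")
            pseed = major_isoform_seed(o, "PASSENGER")
            for seed, label in ((gseed, "guide"), (pseed, "passenger")):
                if seed is None:
                    rows.append(
                        {
                            "target": o.design.site.source_id,
                            "start": o.design.site.start,
                            "strand": label,
                            "seed": "NA",
                            "genes_with_site": "NA",
                            "total_sites": "NA",
                        }
                    )
                    continue
                rep = scan_seed_matches(seed, utrs)
                rows.append(
                    {
                        "target": o.design.site.source_id,
                        "start": o.design.site.start,
                        "strand": label,
                        "seed": seed.hexamer.residues,
                        "genes_with_site": rep.genes_with_site,
                        "total_sites": rep.total_sites,
                    }
                )
        _write_tsv(pd.DataFrame(rows), out / "offtarget.tsv", cfg)
        artifacts["offtarget"] = out / "offtarget.tsv"
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"offtarget: {e}") from e
    return artifacts
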