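"""End-to-end orchestration: simulate -> preprocess -> connect -> NBS ->
associate, with a flat INI configuration, per-stage TSV artifacts and a
checksummed run manifest for reproducibility."""

from __future__ import annotations

import configparser
import hashlib
import io
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical, connectivity, nbs, synthetic
from .atlas import load_atlas
from .bands import CANONICAL_BANDS, get_band
from .preprocess import qc_group_compare

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"

DEFAULT_BANDS = ["lfo", "slow-5", "slow-4", "slow-3", "slow-2"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (INI-serialisable)."""

    out_dir: str = "dmnfc_out"
    seed: int = 0
    bands: list = field(default_factory=lambda: list(DEFAULT_BANDS))
    # cohort
    n_group_a: int = 35
    n_group_b: int = 27
    n_volumes: int = 200
    tr_seconds: float = 2.0
    n_movers: int = 0
    input_dir: str = ""  # read an existing cohort instead of simulating
    # preprocess
    n_discard: int = 4
    filter_mode: str = "butterworth"
    fd_threshold_mm: float = 0.5
    # nbs
    t_threshold: float = 3.2
    n_permutations: int = 10_000
    tail: str = "both"
    # association
    mmse_column: str = "MMSE"
    verbosity: str = "INFO"

    def cohort_config(self) -> synthetic.CohortConfig:
        return synthetic.CohortConfig(
            n_group_a=self.n_group_a,
            n_group_b=self.n_group_b,
            n_volumes=self.n_volumes,
            tr_seconds=self.tr_seconds,
            n_movers=self.n_movers,
            filter_mode=self.filter_mode,
            seed=self.seed,
        )

    def nbs_config(self) -> nbs.NbsConfig:
        return nbs.NbsConfig(
            t_threshold=self.t_threshold,
            n_permutations=self.n_permutations,
            tail=self.tail,
            seed=self.seed,
        )

    def to_ini(self) -> str:
        cp = configparser.ConfigParser()
        cp["run"] = {
            "out_dir": self.out_dir,
            "seed": str(self.seed),
            "bands": ",".join(self.bands),
            "verbosity": self.verbosity,
        }
        cp["cohort"] = {
            "n_group_a": str(self.n_group_a),
            "n_group_b": str(self.n_group_b),
            "n_volumes": str(self.n_volumes),
            "tr_seconds": str(self.tr_seconds),
            "n_movers": str(self.n_movers),
            "input_dir": self.input_dir,
        }
        cp["preprocess"] = {
            "n_discard": str(self.n_discard),
            "filter_mode": self.filter_mode,
            "fd_threshold_mm": str(self.fd_threshold_mm),
        }
        cp["nbs"] = {
            "t_threshold": str(self.t_threshold),
            "n_permutations": str(self.n_permutations),
            "tail": self.tail,
        }
        cp["association"] = {"mmse_column": self.mmse_column}
        buf = io.StringIO()
        cp.write(buf)
        return buf.getvalue()

    @classmethod
    def from_ini(cls, path: str | Path) -> "RunConfig":
        cp = configparser.ConfigParser()
        with open(path) as fh:
            cp.read_file(fh)
        cfg = cls()
        sections = {
            "run": ["out_dir", "seed", "bands", "verbosity"],
            "cohort": ["n_group_a", "n_group_b", "n_volumes", "tr_seconds",
                       "n_movers", "input_dir"],
            "preprocess": ["n_discard", "filter_mode", "fd_threshold_mm"],
            "nbs": ["t_threshold", "n_permutations", "tail"],
            "association": ["mmse_column"],
        }
        types = {f.name: f.type for f in fields(cls)}
        for section, keys in sections.items():
            if section not in cp:
                continue
            for key in keys:
                if key not in cp[section]:
                    continue
                raw = cp[section][key]
                if key == "bands":
                    cfg.bands = [b.strip() for b in raw.split(",") if b.strip()]
                elif types[key] == "int":
                    setattr(cfg, key, int(raw))
                elif types[key] == "float":
                    setattr(cfg, key, float(raw))
                else:
                    setattr(cfg, key, raw)
        for b in cfg.bands:
            get_band(b)  # validate early
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_ini().encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def write_nbs_outputs(result: nbs.NbsResult, band: str, out: Path,
                      atlas) -> list[Path]:
    """Components, null-distribution and t-matrix TSVs for one band."""
    names = atlas.names
    rows = []
    for tail, comps in result.components.items():
        for ci, comp in enumerate(comps):
            for i, j in comp.edges:
                rows.append(
                    {
                        "tail": tail,
                        "component": ci,
                        "roi_i": names[i - 1],
                        "roi_j": names[j - 1],
                        "t": result.stats.t[i - 1, j - 1],
                        "size_k": comp.size_k,
                        "p_fwe": comp.p_fwe,
                    }
                )
    written = [
        _write_tsv(
            pd.DataFrame(
                rows,
                columns=["tail", "component", "roi_i", "roi_j", "t",
                         "size_k", "p_fwe"],
            ),
            out / f"nbs_components_{band}.tsv",
        )
    ]
    null_df = pd.DataFrame(
        {
            tail: pd.Series(sizes)
            for tail, sizes in result.null_max_sizes.items()
        }
    )
    written.append(_write_tsv(null_df, out / f"nbs_null_{band}.tsv"))
    tdf = pd.DataFrame(result.stats.t, columns=names)
    written.append(_write_tsv(tdf, out / f"nbs_tmatrix_{band}.tsv"))
    return written


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage per band and write a checksummed manifest.

    Returns the manifest dict (also written to ``manifest.txt``).  A rerun
    with the same config and seed reproduces identical TSV artifacts.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity, "INFO"))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = load_atlas()
    written: list[Path] = []

    stage = "simulate"
    try:
        if config.input_dir:
            sessions, participants, truth = synthetic.read_cohort(
                config.input_dir
            )
        else:
            sessions, participants, truth = synthetic.generate_cohort(
                config.cohort_config()
            )
            written += synthetic.write_cohort(
                sessions, participants, truth, out / "cohort"
            )

        stage = "connect"
        bands = [get_band(b) for b in config.bands]
        matrices, qc = connectivity.cohort_connectivity(
            sessions,
            bands,
            atlas=atlas,
            n_discard=config.n_discard,
            filter_mode=config.filter_mode,  # type: ignore[arg-type]
            fd_threshold_mm=config.fd_threshold_mm,
        )
        written.append(_write_tsv(qc, out / "qc_report.tsv"))
        t_fd, p_fd = qc_group_compare(qc, "mean_fd")
        t_dv, p_dv = qc_group_compare(qc, "mean_dvars")
        long = connectivity.matrices_to_long(matrices, atlas)
        written.append(_write_tsv(long, out / "connectivity_long.tsv"))
        for m in matrices:
            df = pd.DataFrame(m.z, columns=atlas.names)
            written.append(
                _write_tsv(
                    df, out / "matrices" / f"{m.subject_id}_{m.band}_z.tsv"
                )
            )

        stage = "nbs"
        kept = {m.subject_id for m in matrices}
        part_kept = participants[participants["participant_id"].isin(kept)]
        label_of = dict(
            zip(part_kept["participant_id"], part_kept["group"])
        )
        results: dict[str, nbs.NbsResult] = {}
        sig_summary = {}
        for band in config.bands:
            band_ms = [m for m in matrices if m.band == band]
            labels = [label_of[m.subject_id] for m in band_ms]
            res = nbs.run_nbs(
                [m.z for m in band_ms], labels, config.nbs_config(),
                group_a=truth.config.group_a,
            )
            results[band] = res
            written += write_nbs_outputs(res, band, out, atlas)
            sig_summary[band] = [
                {"tail": tail, "size_k": c.size_k, "p_fwe": c.p_fwe,
                 "edges": c.edges}
                for tail, c in res.significant_components()
            ]

        stage = "associate"
        assoc = clinical.associate_all(
            results, matrices, part_kept, mmse_column=config.mmse_column
        )
        written.append(_write_tsv(assoc, out / "associations.tsv"))
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "bands": config.bands,
        "n_subjects_analyzed": len(kept),
        "qc_group_compare": {"fd": [t_fd, p_fd], "dvars": [t_dv, p_dv]},
        "significant_components": sig_summary,
        "files": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(written)
            if p.suffix == ".tsv" or p.name == "truth.json"
        },
    }
    (out / "manifest.txt").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str)
    )
    logger.info("pipeline complete: %d files under %s", len(written), out)
    return manifest
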