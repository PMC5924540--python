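"""End-to-end orchestration: simulate -> haplotypes -> diversity ->
resample -> network -> skyline, with a self-describing run manifest.

Every stage writes plain-text outputs into the run directory and the
manifest records seeds, parameters (including defaults), input checksums
and per-stage output paths, so a run can be audited and reproduced from
the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .alignment import read_alignment
from .diversity import summarize
from .genealogy import Genealogy
from .haplotypes import collapse_haplotypes
from .network import build_mj
from .resampling import boxplot_summary, group_subsample_diversity, rank_groups
from .simulate import make_study_fixture
from .skyline import ESS_GATE, fit_skyline, skyline_summary

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_inputs", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Plain-text configuration for a pipeline run.

    Either ``alignment``/``dates`` point at real inputs, or
    ``simulate=True`` generates the bundled study-design fixture first.
    Seeds are mandatory for stochastic stages (no wall-clock seeding).
    """

    out_dir: str = "mitopop_run"
    # inputs
    alignment: Optional[str] = None
    dates: Optional[str] = None
    genealogy: Optional[str] = None
    groups: Optional[str] = None          # TSV id -> group for resampling
    simulate: bool = False
    scale: float = 1.0
    # stage parameters
    seed: int = 1
    k: int = 10
    replicates: int = 100
    epsilon: int = 0
    skyline_groups: int = 10
    skyline_grouping: str = "even-events"
    chain_length: int = 30000
    generation_time: float = 12.0
    missing_policy: str = "exclude-missing"
    stages: list[str] = field(
        default_factory=lambda: ["haplotypes", "diversity", "network", "skyline"]
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _read_groups(path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sid, grp = line.split("\t")[:2]
            out[sid] = grp
    return out


def validate_inputs(config: PipelineConfig) -> dict:
    """Check inputs against stage requirements; report, don't raise.

    Returns ``{"errors": [...], "warnings": [...]}``.  Errors are
    conditions that will abort a run (missing files, group smaller than
    k, more skyline groups than coalescent events); warnings flag data
    features worth knowing about (e.g. a high missing-column fraction).
    """
    errors: list[str] = []
    warnings_: list[str] = []
    aln = None
    if not config.simulate:
        if config.alignment is None:
            errors.append("no alignment given and simulation not requested")
        elif not Path(config.alignment).exists():
            errors.append(f"alignment file not found: {config.alignment}")
        else:
            try:
                aln = read_alignment(config.alignment, config.dates)
            except (ValueError, KeyError) as exc:
                errors.append(f"alignment unreadable: {exc}")
        if config.dates is not None and not Path(config.dates).exists():
            errors.append(f"dates file not found: {config.dates}")

    if aln is not None:
        miss_cols = int(aln.missing_mask().any(axis=0).sum())
        if miss_cols:
            warnings_.append(
                f"{miss_cols}/{aln.n_sites} columns contain missing data "
                f"({100 * miss_cols / aln.n_sites:.1f}%)"
            )
        if "skyline" in config.stages:
            if config.genealogy is None and not config.simulate:
                errors.append("skyline stage requires a dated genealogy")
            if np.any(aln.ages > 0) and config.dates is None:
                errors.append("heterochronous data require a dates file")
            n = aln.n_sequences
            if config.skyline_groups > n - 1:
                errors.append(
                    f"skyline_groups={config.skyline_groups} exceeds n-1={n - 1}"
                )
        if "resample" in config.stages and config.groups:
            groups = _read_groups(config.groups)
            from collections import Counter

            sizes = Counter(groups.values())
            for g, size in sorted(sizes.items()):
                if size < config.k:
                    errors.append(f"group {g!r} has {size} members, fewer than k={config.k}")
    return {"errors": errors, "warnings": warnings_}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the manifest (also written to ``<out_dir>/manifest.json``).
    Stage failures abort with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logging.getLogger("mitopop").addHandler(handler)

    manifest: dict = {
        "tool": "mitopop",
        "version": __version__,
        "config": asdict(config),
        "stages": {},
    }
    report = validate_inputs(config)
    manifest["validation"] = report
    if report["errors"]:
        raise RuntimeError(f"input validation failed: {report['errors']}")

    stage = "setup"
    try:
        genealogy = None
        if config.simulate:
            stage = "simulate"
            fixture = make_study_fixture(config.seed, scale=config.scale)
            paths = fixture.write(out / "fixture")
            aln = fixture.alignment
            genealogy = fixture.genealogy
            manifest["stages"]["simulate"] = {
                "seed": config.seed,
                "scale": config.scale,
                "outputs": {k: str(v) for k, v in paths.items()},
                "checksums": {k: _sha256(v) for k, v in paths.items()},
            }
        else:
            aln = read_alignment(config.alignment, config.dates)
            manifest["inputs"] = {
                "alignment": {"path": config.alignment, "sha256": _sha256(Path(config.alignment))}
            }
            if config.genealogy:
                genealogy = Genealogy.from_newick(
                    config.genealogy,
                    tip_ages={i: a for i, a in zip(aln.ids, aln.ages)},
                )

        if "haplotypes" in config.stages:
            stage = "haplotypes"
            ht = collapse_haplotypes(aln, config.missing_policy)
            ht_path = out / "haplotypes.tsv"
            ht.write_tsv(ht_path)
            vs_path = out / "variable_sites.tsv"
            with open(vs_path, "w") as fh:
                fh.write("position_1based\n")
                for p in ht.variable_positions:
                    fh.write(f"{p + 1}\n")
            manifest["stages"]["haplotypes"] = {
                "n_haplotypes": len(ht),
                "n_variable_sites": len(ht.variable_positions),
                "outputs": [str(ht_path), str(vs_path)],
                "checksums": [_sha256(ht_path), _sha256(vs_path)],
            }

        if "diversity" in config.stages:
            stage = "diversity"
            panel = summarize(aln, missing_policy=config.missing_policy)
            div_path = out / "diversity.tsv"
            with open(div_path, "w") as fh:
                cols = list(panel[0].as_dict())
                fh.write("\t".join(cols) + "\n")
                for row in panel:
                    d = row.as_dict()
                    fh.write("\t".join(f"{d[c]:.6g}" if isinstance(d[c], float) else str(d[c]) for c in cols) + "\n")
            manifest["stages"]["diversity"] = {
                "outputs": [str(div_path)],
                "checksums": [_sha256(div_path)],
            }

        if "resample" in config.stages and config.groups:
            stage = "resample"
            membership = _read_groups(config.groups)
            group_alns = {
                g: aln.subset([i for i in aln.ids if membership.get(i) == g])
                for g in sorted(set(membership.values()))
            }
            dist = group_subsample_diversity(
                group_alns, k=config.k, replicates=config.replicates, seed=config.seed
            )
            rep_path = out / "resample_replicates.tsv"
            dist.write_tsv(rep_path)
            box_path = out / "resample_boxplots.tsv"
            with open(box_path, "w") as fh:
                fh.write("group\tmedian\tq1\tq3\twhisker_low\twhisker_high\toutliers\n")
                for b in boxplot_summary(dist):
                    outl = ",".join(f"{x:.6g}" for x in b.outliers)
                    fh.write(
                        f"{b.group}\t{b.median:.6g}\t{b.q1:.6g}\t{b.q3:.6g}"
                        f"\t{b.whisker_low:.6g}\t{b.whisker_high:.6g}\t{outl}\n"
                    )
            manifest["stages"]["resample"] = {
                "k": config.k,
                "replicates": config.replicates,
                "seed": config.seed,
                "ranking": [r.group for r in rank_groups(dist)],
                "outputs": [str(rep_path), str(box_path)],
                "checksums": [_sha256(rep_path), _sha256(box_path)],
            }

        if "network" in config.stages:
            stage = "network"
            ht = collapse_haplotypes(aln, config.missing_policy)
            net = build_mj(ht, epsilon=config.epsilon)
            e_path, n_path = out / "network_edges.tsv", out / "network_nodes.tsv"
            net.write_edges_tsv(e_path)
            net.write_nodes_tsv(n_path)
            manifest["stages"]["network"] = {
                "epsilon": config.epsilon,
                "n_observed": len(net.observed),
                "n_medians": len(net.medians),
                "parsimony_length": net.parsimony_length(),
                "outputs": [str(e_path), str(n_path)],
                "checksums": [_sha256(e_path), _sha256(n_path)],
            }

        if "skyline" in config.stages:
            stage = "skyline"
            if genealogy is None:
                raise RuntimeError("skyline stage requires a dated genealogy")
            post = fit_skyline(
                genealogy,
                m=config.skyline_groups,
                grouping=config.skyline_grouping,
                chain_length=config.chain_length,
                seed=config.seed,
            )
            trace_path = out / "skyline_trace.csv"
            post.write_trace_csv(trace_path)
            traj = skyline_summary(post, gen_time=config.generation_time)
            traj_path = out / "skyline_trajectory.tsv"
            traj.to_csv(traj_path, sep="\t", index=False)
            ess_vals = post.ess()
            manifest["stages"]["skyline"] = {
                "m": config.skyline_groups,
                "chain_length": config.chain_length,
                "seed": config.seed,
                "min_ess": float(ess_vals.min()),
                "converged": bool(np.all(ess_vals > ESS_GATE)),
                "acceptance": [float(a) for a in post.acceptance],
                "outputs": [str(trace_path), str(traj_path)],
                "checksums": [_sha256(trace_path), _sha256(traj_path)],
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logging.getLogger("mitopop").removeHandler(handler)
        handler.close()

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
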