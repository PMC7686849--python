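"""End-to-end orchestration: qc -> ld -> phase -> assoc -> fst -> pbs-scan
-> bifurcate from one declarative config, with a reproducible run manifest.

Each stage writes TSV (or VCF) outputs and is independently re-runnable;
the manifest records the package version, seeds, parameters and a sha256
per output so that identical config + seed means hash-identical runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import bonferroni_threshold, covariate_frame, encode, glm_gaussian, nb_glm
from .bifurcation import build_bifurcation, extended_homozygosity
from .core_data import (
    GenotypeMatrix,
    genotype_counts,
    read_genotype_vcf,
    read_phenotypes_tsv,
    write_phased_vcf,
)
from .differentiation import PopFreqTable, fst_permutation_p, sliding_windows, windows_frame
from .ld import ld_matrix
from .phasing import em_phase, haplotype_table, panel_from_phasing
from .popstats import snp_summary

log = logging.getLogger("haploscan")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    vcf: str
    phenotypes: str
    out_dir: str
    snp_ids: Sequence[str] | None = None
    strata: Sequence[str] = ("cohort",)
    phenotype_field: str = "hb"
    models: Sequence[str] = ("additive", "dominant")
    covariates: Sequence[str] = ("age", "sex", "altitude")
    alpha: float = 0.05
    window_bp: int = 5000
    step_bp: int = 5000
    n_permutations: int = 2000
    seed: int = 0
    # optional inputs for the differentiation scan
    freqs_tsv: str | None = None
    sizes_tsv: str | None = None
    triplet: Sequence[str] | None = None
    # bifurcation settings
    core_snp: str | None = None
    core_allele: str | None = None
    fst_stratum: str = "cohort"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def validate(self) -> None:
        for p in (self.vcf, self.phenotypes, self.freqs_tsv, self.sizes_tsv):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        if not (self.window_bp >= self.step_bp > 0):
            raise ValueError("require window >= step > 0")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _attach_metadata(gm: GenotypeMatrix, pheno) -> GenotypeMatrix:
    from .core_data import SampleRecord

    samples = []
    for s in gm.samples:
        row = pheno.frame.reindex([s.sample_id]).iloc[0]
        samples.append(
            SampleRecord(
                s.sample_id,
                cohort=row.get("cohort") if isinstance(row.get("cohort"), str) else None,
                sex=row.get("sex") if isinstance(row.get("sex"), str) else None,
                age=None if pd.isna(row.get("age")) else float(row.get("age")),
                altitude=None
                if pd.isna(row.get("altitude"))
                else float(row.get("altitude")),
            )
        )
    return GenotypeMatrix(samples, gm.snps, gm.dosage, gm.missing, gm.phased_input)


def stage_qc(gm: GenotypeMatrix, cfg: RunConfig, out: Path) -> Path:
    rows = []
    strata: list[tuple[str, Mapping[str, str] | None]] = [("entire", None)]
    for key in cfg.strata:
        for val in sorted(
            {getattr(s, key) for s in gm.samples if getattr(s, key, None)}
        ):
            strata.append((f"{key}={val}", {key: val}))
    for snp in gm.snps:
        for label, flt in strata:
            n_aa, n_ab, n_bb, n_miss = genotype_counts(gm, snp.snp_id, flt)
            if n_aa + n_ab + n_bb == 0:
                continue
            s = snp_summary((n_aa, n_ab, n_bb), snp.snp_id, label)
            rows.append(
                {
                    "snp_id": s.snp_id,
                    "stratum": s.stratum,
                    "n": s.n,
                    "n_missing": n_miss,
                    "major": snp.allele_a,
                    "minor": snp.allele_b,
                    "freq_major": s.freq_a,
                    "freq_minor": s.freq_b,
                    "count_major": s.count_a,
                    "count_minor": s.count_b,
                    "h_obs": s.h_obs,
                    "h_exp": s.h_exp,
                    "hwe_p": s.hwe_p,
                }
            )
    path = out / "qc_snp_summary.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def stage_ld(gm: GenotypeMatrix, out: Path) -> Path:
    res = ld_matrix(gm, phased=False)
    frame = pd.DataFrame(
        {
            "snp1": [r.snp1 for r in res],
            "snp2": [r.snp2 for r in res],
            "d": [r.d for r in res],
            "d_prime": [r.d_prime for r in res],
            "r2": [r.r2 for r in res],
            "n_chrom": [r.n_chrom for r in res],
            "chi2_p": [r.chi2_p for r in res],
        }
    )
    path = out / "ld_pairs.tsv"
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def stage_phase(gm, pheno, cfg: RunConfig, out: Path):
    pr = em_phase(gm, seed=cfg.seed)
    panel = panel_from_phasing(pr, gm)
    vcf_path = out / "phased.vcf"
    write_phased_vcf(panel, vcf_path)
    table = haplotype_table(panel, pheno, cfg.phenotype_field)
    tsv_path = out / "haplotype_table.tsv"
    table.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    return pr, panel, table, [vcf_path, tsv_path]


def stage_assoc(gm, pheno, table, cfg: RunConfig, out: Path) -> list[Path]:
    sample_ids = [s.sample_id for s in gm.samples]
    y = pheno.frame.reindex(sample_ids)[cfg.phenotype_field].to_numpy(dtype=float)
    cov = covariate_frame(pheno, sample_ids)
    cov = cov[[c for c in cfg.covariates if c in cov.columns]]
    rows = []
    m = len(gm.snps)
    for snp in gm.snps:
        for model in cfg.models:
            enc = encode(gm, snp.snp_id, model)
            xs = enc.series(sample_ids).to_numpy()
            fit = glm_gaussian(y, xs, cov)
            rows.append(
                {
                    "snp_id": snp.snp_id,
                    "model": model,
                    "beta": fit.beta("x"),
                    "se": float(fit.params.loc["x", "se"]),
                    "p": fit.p("x"),
                    "n": fit.n,
                    "significant": fit.p("x") < bonferroni_threshold(cfg.alpha, m),
                }
            )
    snp_path = out / "assoc_snp.tsv"
    pd.DataFrame(rows).to_csv(snp_path, sep="\t", index=False, float_format="%.6g")

    ok = table.dropna(subset=["pheno_mean"])
    nb = nb_glm(ok["count"].to_numpy(), ok["pheno_mean"].to_numpy())
    nb_path = out / "assoc_haplotype_nb.tsv"
    nb_frame = nb.params.copy()
    nb_frame["theta"] = nb.dispersion
    nb_frame["n_haplotypes"] = nb.n
    nb_frame.to_csv(nb_path, sep="\t", float_format="%.6g")
    return [snp_path, nb_path]


def stage_fst(panel, gm, cfg: RunConfig, out: Path) -> Path:
    labels = {
        s.sample_id: getattr(s, cfg.fst_stratum, None) for s in gm.samples
    }
    pairs_by_sample: dict[str, list[str]] = {}
    for h, c in zip(panel.haplotypes, panel.carriers):
        pairs_by_sample.setdefault(c, []).append(h)
    sids = [s for s in pairs_by_sample if labels.get(s)]
    hap_pairs = [tuple(pairs_by_sample[s]) for s in sids]
    labs = [labels[s] for s in sids]
    res = fst_permutation_p(
        hap_pairs, labs, n_perm=cfg.n_permutations, seed=cfg.seed
    )
    path = out / "haplotype_fst.tsv"
    pd.DataFrame(
        [
            {
                "pop_a": res.pop_a,
                "pop_b": res.pop_b,
                "fst": res.fst,
                "p_value": res.p_value,
                "n_permutations": res.n_permutations,
            }
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def load_pop_freq_table(freqs_tsv: str, sizes_tsv: str) -> PopFreqTable:
    frame = pd.read_csv(freqs_tsv, sep="\t")
    sizes = pd.read_csv(sizes_tsv, sep="\t")
    pops = [c for c in frame.columns if c != "position"]
    size_map = dict(zip(sizes["population"], sizes["haploid_n"]))
    return PopFreqTable(
        pops=pops,
        positions=frame["position"].to_numpy(),
        freqs=frame[pops].to_numpy().T,
        sizes=np.array([size_map[p] for p in pops]),
    )


def stage_pbs_scan(cfg: RunConfig, out: Path) -> Path | None:
    if cfg.freqs_tsv is None or cfg.sizes_tsv is None:
        return None
    pft = load_pop_freq_table(cfg.freqs_tsv, cfg.sizes_tsv)
    triplet = list(cfg.triplet) if cfg.triplet else pft.pops[:3]
    stats = sliding_windows(pft, triplet, cfg.window_bp, cfg.step_bp)
    frame = windows_frame(stats, triplet)
    path = out / "pbs_windows.tsv"
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def stage_bifurcate(panel, cfg: RunConfig, out: Path) -> list[Path]:
    core_snp = cfg.core_snp or panel.snps[-1].snp_id
    core_allele = cfg.core_allele or max(
        set(panel.alleles_at(core_snp)),
        key=panel.alleles_at(core_snp).count,
    )
    paths = []
    for direction in ("upstream", "downstream"):
        tree = build_bifurcation(panel, core_snp, core_allele, direction)
        frame = tree.to_frame()
        ehh = extended_homozygosity(tree)
        frame["ehh_at_depth"] = frame["depth"].map(
            lambda d: ehh[d] if d < len(ehh) else np.nan
        )
        path = out / f"bifurcation_{direction}.tsv"
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
        paths.append(path)
    return paths


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns (and writes) the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    stage = "load"
    try:
        pheno = read_phenotypes_tsv(config.phenotypes)
        gm = read_genotype_vcf(config.vcf, panel_snp_ids=config.snp_ids)
        gm = _attach_metadata(gm, pheno)
        stage = "qc"
        log.info("stage=qc")
        outputs.append(stage_qc(gm, config, out))
        stage = "ld"
        log.info("stage=ld")
        outputs.append(stage_ld(gm, out))
        stage = "phase"
        log.info("stage=phase")
        pr, panel, table, paths = stage_phase(gm, pheno, config, out)
        outputs.extend(paths)
        stage = "assoc"
        log.info("stage=assoc")
        outputs.extend(stage_assoc(gm, pheno, table, config, out))
        stage = "fst"
        log.info("stage=fst")
        outputs.append(stage_fst(panel, gm, config, out))
        stage = "pbs-scan"
        log.info("stage=pbs-scan")
        p = stage_pbs_scan(config, out)
        if p is not None:
            outputs.append(p)
        stage = "bifurcate"
        log.info("stage=bifurcate")
        outputs.extend(stage_bifurcate(panel, config, out))
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed on inputs "
            f"vcf={config.vcf} phenotypes={config.phenotypes}: {exc}"
        ) from exc
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "params": {
            "window_bp": config.window_bp,
            "step_bp": config.step_bp,
            "n_permutations": config.n_permutations,
            "models": list(config.models),
            "covariates": list(config.covariates),
            "alpha": config.alpha,
        },
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
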