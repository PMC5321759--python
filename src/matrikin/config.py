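"""Run configuration: every pipeline threshold in one round-trippable record.

Defaults are the published analysis parameters: consensus 2x non-redundant
coverage (4x for the damage-restricted consensus) with 80% site identity,
reads <20 bp removed, mapping-quality cutoffs 30 (mtDNA capture
bleed-through) and 37 (SNP capture), PMD score threshold 3, kinship
correction constant b = 0.105, 5-Mb jackknife blocks, Ry call thresholds
0.016 / 0.075, HPD levels 68.2% / 95.4%, and the 750-1250 CE simulation
design (10 dates +/- 20 14C yr every 25 yr, 20-yr bins).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass
class RunConfig:
    # seeds, one per stage so stages can be rerun standalone
    seed: int = 0

    # synthetic-data generation
    n_snp_sites: int = 50_000
    snp_coverage: float = 0.5
    snp_error: float = 0.001
    cpg_fraction: float = 0.20
    freq_low: float = 0.05
    freq_high: float = 0.95
    mt_coverage: float = 20.0
    mt_error: float = 0.001
    damage_d0: float = 0.4
    damage_lambda: float = 0.3
    male_ry: float = 0.09

    # damage / consensus
    profile_k: int = 25
    pmd_threshold: float = 3.0
    min_read_length: int = 20
    min_mapq_mt: int = 30
    min_mapq_snp: int = 37
    consensus_min_cov: int = 2
    consensus_pmd_min_cov: int = 4
    consensus_identity: float = 0.80

    # relatedness
    b: float = 0.105
    block_size: int = 5_000_000
    z_threshold: float = 3.0

    # sex inference
    ry_female_max: float = 0.016
    ry_male_min: float = 0.075

    # chronology
    hpd_levels: tuple = (0.682, 0.954)
    delta_r: float = 234.0
    sigma_delta_r: float = 23.0
    mcmc_iter: int = 20_000
    mcmc_chains: int = 4
    mcmc_burn_in: float = 0.5
    sim_start_ce: float = 750.0
    sim_end_ce: float = 1250.0
    sim_step: float = 25.0
    sim_dates_per_point: int = 10
    sim_sigma: float = 20.0
    sim_bin_width: float = 20.0

    # file paths (optional; used by the CLI)
    curve_file: str | None = None

    def to_yaml(self, path=None) -> str:
        d = dataclasses.asdict(self)
        d["hpd_levels"] = list(self.hpd_levels)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(source)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "hpd_levels" in data:
            data["hpd_levels"] = tuple(data["hpd_levels"])
        return cls(**data)
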