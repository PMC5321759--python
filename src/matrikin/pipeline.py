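"""End-to-end orchestration of the synthetic matriline analysis.

``run_all`` wires the stages together on generated data with known ground
truth: a nine-member matriline's mitochondrial read stacks are damage-
profiled, masked, deduplicated and called to consensus (full and
PMD-restricted), the haplogroup-B deletion is checked, pairwise mitogenome
distances are computed, X/Y counts are sexed, a pedigree's SNP reads are
run through the kinship estimator, and a synthetic calibration curve
drives date calibration and the plateau-bias simulation.  Each stage is
also callable on its own (see :mod:`matrikin.cli`).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import chronology, consensus_mt, damage, relatedness, sex_inference
from . import synthetic_data as synth
from .config import RunConfig

log = logging.getLogger("matrikin")


class StageError(RuntimeError):
    """Raised when a stage fails; names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def default_matriline(n_members: int = 9, seed: int = 0) -> synth.MtHaplotypeSpec:
    """Nine individuals sharing one mitogenome (a single matriline), all
    carrying the haplogroup-B 9-bp deletion."""
    founder = synth.make_mt_founder(seed=seed)
    names = [f"ind{i+1}" for i in range(n_members)]
    return synth.MtHaplotypeSpec(
        founder=founder,
        mutations={name: () for name in names},
        b_deletion={name: True for name in names},
    )


def default_pedigree() -> synth.PedigreeSpec:
    """Three-generation matriline plus an unrelated pair: grandmother GM,
    her daughter MO (father F0), MO's son SON and daughter DAU (father F1),
    and two unrelated founders U1, U2."""
    return synth.PedigreeSpec(
        individuals=("GM", "F0", "MO", "F1", "SON", "DAU", "U1", "U2"),
        parents={
            "MO": ("GM", "F0"),
            "SON": ("MO", "F1"),
            "DAU": ("MO", "F1"),
        },
    )


def mt_stage(reads: pd.DataFrame, truth_len: int, cfg: RunConfig,
             reference: str) -> dict:
    """Filter -> dedup -> profile -> mask -> consensus (+PMD consensus) for
    one individual's mitochondrial read stack, in the sample frame."""
    filtered = consensus_mt.filter_reads(reads, cfg.min_read_length, cfg.min_mapq_mt)
    unique = damage.dedup(filtered)
    profile = damage.terminal_profile(unique, reference, k=cfg.profile_k)
    profile = damage.fit_lambda(profile)
    if profile.flat:
        k = 1
    else:
        k = damage.mask_width_95(profile.lam)
    pmd_reads = damage.pmd_filter(unique, reference, profile, cfg.pmd_threshold)
    masked = damage.mask_terminal(unique, k)
    masked_pmd = damage.mask_terminal(pmd_reads, k)
    cons = consensus_mt.call_consensus(masked, truth_len,
                                       cfg.consensus_min_cov, cfg.consensus_identity)
    cons_pmd = consensus_mt.call_pmd_consensus(masked_pmd, truth_len,
                                               cfg.consensus_pmd_min_cov,
                                               cfg.consensus_identity)
    agree, total = consensus_mt.consensus_concordance(cons, cons_pmd)
    return {
        "profile": profile, "mask_k": k,
        "consensus": cons, "pmd_consensus": cons_pmd,
        "pmd_reads_kept": len(pmd_reads), "reads_used": len(unique),
        "pmd_concordant": agree, "pmd_co_called": total,
    }


def run_all(cfg: RunConfig, outdir: str | Path) -> dict:
    """Run every stage on synthetic inputs and write a report bundle.

    Returns the report dict; writes CSV/FASTA/JSON outputs plus a manifest
    under ``outdir``.  Any stage failure raises StageError naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": cfg.to_yaml()}
    manifest: list[str] = []
    rng = np.random.default_rng(cfg.seed)

    # --- mitochondrial stage: matriline consensus + distances -------------
    try:
        hap = default_matriline(seed=cfg.seed)
        names = list(hap.mutations)
        # an outgroup lineage without the deletion, two private substitutions
        outgroup = synth.MtHaplotypeSpec(
            founder=hap.founder,
            mutations={"out1": ((5_000, "A"), (12_000, "C"))},
            b_deletion={"out1": False},
        )
        consensi: dict[str, str] = {}
        mt_summary = []
        for name in names + ["out1"]:
            spec = outgroup if name == "out1" else hap
            truth = spec.lineage_sequence(name)
            p = synth.SimReadParams(coverage=cfg.mt_coverage, error=cfg.mt_error,
                                    d0=cfg.damage_d0, lam=cfg.damage_lambda,
                                    seed=int(rng.integers(2**31)))
            reads = synth.simulate_mt_reads(truth, p)
            res = mt_stage(reads, len(truth), cfg, truth)
            cons, rep = consensus_mt.correct_b_deletion(res["consensus"], hap.founder)
            consensi[name] = cons.sequence
            mt_summary.append({
                "individual": name,
                "lambda": res["profile"].lam, "d0": res["profile"].d0,
                "mask_k": res["mask_k"],
                "called_fraction": cons.called_fraction,
                "b_deletion": rep.detected, "deletion_length": rep.length,
                "pmd_concordance": (res["pmd_concordant"] / res["pmd_co_called"]
                                    if res["pmd_co_called"] else float("nan")),
            })
        dm = consensus_mt.pairwise_distances(consensi)
        dm.to_csv(outdir / "mt_distances.csv")
        manifest.append("mt_distances.csv")
        consensus_mt.write_fasta(consensi, outdir / "mt_consensus.fasta")
        manifest.append("mt_consensus.fasta")
        mt_df = pd.DataFrame(mt_summary)
        mt_df.to_csv(outdir / "mt_summary.csv", index=False)
        manifest.append("mt_summary.csv")
        report["mt"] = {
            "bp_analysed": dm.bp_analysed,
            "matriline_max_distance": int(
                dm.matrix.loc[names, names].to_numpy().max()),
            "summary": mt_df.to_dict("records"),
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError("consensus_mt", str(exc)) from exc

    # --- genetic sex ------------------------------------------------------
    try:
        truth_sex = {f"ind{i+1}": ("female" if i % 2 == 0 else "male")
                     for i in range(len(names))}
        counts = []
        for i, name in enumerate(names):
            n_y, n_xy = synth.simulate_xy_counts(
                truth_sex[name], n_xy=2_000, male_ry=cfg.male_ry,
                seed=cfg.seed * 100 + i)
            counts.append({"individual": name, "n_y": n_y, "n_xy": n_xy})
        sex_df = sex_inference.estimate_sexes(
            pd.DataFrame(counts), cfg.ry_female_max, cfg.ry_male_min)
        osteo = pd.DataFrame({"individual": names,
                              "sex": [truth_sex[n] for n in names]})
        frac, disc = sex_inference.concordance(sex_df, osteo)
        sex_df.to_csv(outdir / "sex_estimates.csv", index=False)
        manifest.append("sex_estimates.csv")
        report["sex"] = {"concordance": frac, "n_discrepant": len(disc)}
    except Exception as exc:
        raise StageError("sex_inference", str(exc)) from exc

    # --- nuclear kinship --------------------------------------------------
    try:
        ped = default_pedigree()
        gt = synth.simulate_pedigree(ped, cfg.n_snp_sites,
                                     freq_low=cfg.freq_low, freq_high=cfg.freq_high,
                                     cpg_fraction=cfg.cpg_fraction, seed=cfg.seed)
        reads = synth.sample_snp_reads(gt, synth.SimReadParams(
            coverage=cfg.snp_coverage, error=cfg.snp_error,
            d0=cfg.damage_d0, lam=cfg.damage_lambda, seed=cfg.seed + 1))
        kin = relatedness.kin_table(reads, seed=cfg.seed + 2, b=cfg.b,
                                    block_size=cfg.block_size)
        kin["r_true"] = [synth.true_relatedness(ped, a, c)
                         for a, c in zip(kin["id_a"], kin["id_b"])]
        kin.to_csv(outdir / "kinship.csv", index=False)
        manifest.append("kinship.csv")
        report["kinship"] = kin.to_dict("records")
    except Exception as exc:
        raise StageError("relatedness", str(exc)) from exc

    # --- chronology -------------------------------------------------------
    try:
        if cfg.curve_file:
            if not Path(cfg.curve_file).exists():
                raise StageError(
                    "chronology",
                    f"config field curve_file points to a missing file: "
                    f"{cfg.curve_file}")
            curve = chronology.read_curve(cfg.curve_file)
        else:
            curve = synth.make_cal_curve("plateau",
                                         plateau_center_ce=1000.0,
                                         plateau_width=150.0)
        post = chronology.calibrate(
            chronology.C14Date(age_bp=float(curve.mu(chronology.ce_to_bp(825.0))),
                               sigma=20.0),
            curve, levels=cfg.hpd_levels)
        sim = chronology.run_sim_design(
            chronology.SimDesign(cfg.sim_start_ce, cfg.sim_end_ce, cfg.sim_step,
                                 cfg.sim_dates_per_point, cfg.sim_sigma,
                                 cfg.sim_bin_width),
            curve, seed=cfg.seed)
        hist = pd.DataFrame({"bin_lo": sim["bin_edges"][:-1],
                             "bin_hi": sim["bin_edges"][1:],
                             "count": sim["counts"],
                             "z": sim["z_scores"]})
        hist.to_csv(outdir / "c14_sim_histogram.csv", index=False)
        manifest.append("c14_sim_histogram.csv")
        report["chronology"] = {
            "example_date_mean_ce": post.mean_ce(),
            "example_hpd95": post.hpd[max(cfg.hpd_levels)],
            "n_simulated_dates": sim["n_dates"],
            "expected_per_century": sim["expected_per_century"],
            "max_bin_z": float(np.nanmax(sim["z_scores"])),
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError("chronology", str(exc)) from exc

    (outdir / "report.json").write_text(
        json.dumps({k: v for k, v in report.items() if k != "config"},
                   indent=2, default=str))
    manifest.append("report.json")
    (outdir / "MANIFEST.txt").write_text("\n".join(manifest) + "\n")
    log.info("pipeline complete: %d artifacts in %s", len(manifest), outdir)
    return report
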