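"""Two-sample and multivariable MR of neck width and BMD on fracture.

Builds a fully synthetic end-to-end two-sample design: a discovery half
provides exposure summary statistics for FNW and FN-BMD, the other half
provides per-site fracture outcome statistics; instruments are pruned,
harmonized and fed to the estimators.
"""

from fnwpipe import gwas, mr, synth

panel = synth.simulate_reference_panel(1500, 150, block_size=5,
                                       within_block_rho=0.3, seed=11)
arch = synth.default_architecture(panel, n_fnw=15, n_bmd=12,
                                  n_shared_inverse=3, n_shared_positive=1,
                                  target_fnw_variance=0.15,
                                  target_bmd_variance=0.2, seed=12)
cohort = synth.simulate_cohort(
    panel, arch, n=60_000,
    base_hazard={"fn": 4e-3, "trochanteric": 4e-3, "forearm": 6e-3},
    discovery_fraction=0.5, seed=13,
)
disc = cohort.table["discovery_flag"] == 1
discovery, analysis = cohort.subset(disc), cohort.subset(~disc.to_numpy())

ss_fnw = gwas.run_quant_gwas(discovery, gwas.prepare_phenotype(discovery),
                             variants_meta=panel.variants)
ss_bmd = gwas.run_quant_gwas(discovery,
                             gwas.prepare_phenotype(discovery, trait="bmd_sd"),
                             variants_meta=panel.variants)
instruments = sorted(set(mr.select_instruments(ss_fnw, panel))
                     | set(mr.select_instruments(ss_bmd, panel)))
print(f"instruments after genome-wide significance + r² < 0.01 pruning: "
      f"{len(instruments)}")

for site, truth in (("fn", arch.causal_log_or["fnw"]["fn"]),
                    ("forearm", arch.causal_log_or["fnw"]["forearm"])):
    ss_out = gwas.run_binary_gwas(analysis, site, include_prevalent=True,
                                  variants_meta=panel.variants,
                                  variant_subset=instruments)
    ins = mr.harmonize(ss_fnw[ss_fnw["snp"].isin(instruments)],
                       ss_out.dropna(subset=["se"]),
                       second_exposure=ss_bmd[ss_bmd["snp"].isin(instruments)],
                       exposure_name="FNW", second_exposure_name="FN-BMD",
                       outcome_name=site)
    res_fnw, res_bmd = mr.mvmr(ins)
    lo, hi = res_fnw.or_ci95
    print(f"{site:8s} MVMR: FNW OR = {res_fnw.or_:.2f} ({lo:.2f}-{hi:.2f}) "
          f"per SD  [simulated truth OR = {2.718281828**truth:.2f}], "
          f"FN-BMD OR = {res_bmd.or_:.2f}")
    if site == "fn":
        uni = mr.mr_ivw(ins)
        print(f"         univariable IVW (FNW): OR = {uni.or_:.2f}, "
              f"Q p = {uni.q_p:.2f} ({uni.effects_model} effects), "
              f"F = {mr.instrument_strength(ins, 1):.0f}")
print("Wide neck raises femoral-neck fracture risk conditional on BMD, and "
      "shows no effect at the simulated-null forearm site; low BMD raises "
      "risk everywhere.")
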