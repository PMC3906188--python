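"""The four headline qualitative contrasts between the bundled toys.

This is the acceptance contract of the synthetic models, used by the CLI
(``redoxplane reproduce-toy``), the test suite and the results script:

1. coupling     - ethanol production couples to growth in the
                  Crabtree-positive toy under a binding oxygen bound, and
                  does not couple in either toy under unbounded oxygen.
2. availability - gamma_red is in excess at every oxygen-limited phenotype
                  of TOY-SC, but only in a low-oxygen subset for TOY-SS.
3. span         - TOY-SC gains small flux spans (S3 bin) under oxygen
                  limitation; TOY-SS's binned span profile is more
                  invariant (strictly smaller invariance metric).
4. deletion     - deleting the planted NADH-recycling route(s) in TOY-SS
                  flips its availability pattern to the all-excess one.
"""

from __future__ import annotations

from redoxplane.envelope import production_envelope
from redoxplane.fva_span import fva, span_profile
from redoxplane.lp_engine import DEFAULT_CONFIG
from redoxplane.model_core import apply_deletions, set_uptake
from redoxplane.phaseplane import availability_pattern, line_of_optimality, scan
from redoxplane.synthetic_models import (
    SS_RECYCLING_SET,
    toy_cerevisiae,
    toy_stipitis,
)


def four_contrasts(config=DEFAULT_CONFIG) -> dict:
    """Evaluate all four contrasts; ~2000 small LP solves."""
    sc = toy_cerevisiae()
    ss = toy_stipitis()
    out = {}

    # 1. coupling
    loo_sc = float(line_of_optimality(sc, [10.0], config=config)[0])
    env_bound = production_envelope(
        set_uptake(sc, "EX_o2", loo_sc / 2), "EX_eth", config=config
    )
    env_sc_free = production_envelope(sc, "EX_eth", config=config)
    env_ss_free = production_envelope(ss, "EX_eth", config=config)
    ok = (
        env_bound.coupling == "coupled"
        and env_sc_free.coupling == "non_coupled"
        and env_ss_free.coupling == "non_coupled"
    )
    out["coupling"] = {
        "passed": bool(ok),
        "detail": (
            f"SC@O2={loo_sc / 2:.2f}: {env_bound.coupling} "
            f"(min ethanol {env_bound.min_product[-1]:.3f}); "
            f"SC aerobic: {env_sc_free.coupling}; "
            f"SS aerobic: {env_ss_free.coupling}"
        ),
        "sc_bound_min_ethanol": float(env_bound.min_product[-1]),
        "sc_max_growth_aerobic": float(env_sc_free.max_growth),
        "ss_max_growth_aerobic": float(env_ss_free.max_growth),
    }

    # 2. availability pattern
    pat_sc = availability_pattern(scan(sc, config=config))
    pat_ss = availability_pattern(scan(ss, config=config))
    ok = pat_sc.all_excess_o2_limited and pat_ss.subset_excess
    out["availability"] = {
        "passed": bool(ok),
        "detail": (
            f"SC excess fraction {pat_sc.fraction_excess:.3f} "
            f"(all_excess={pat_sc.all_excess_o2_limited}); "
            f"SS excess fraction {pat_ss.fraction_excess:.3f} "
            f"(subset={pat_ss.subset_excess})"
        ),
        "sc_fraction_excess": pat_sc.fraction_excess,
        "ss_fraction_excess": pat_ss.fraction_excess,
    }

    # 3. span behaviour
    s3_low = fva(set_uptake(sc, "EX_o2", 2.0), config=config).bin_counts["S3"]
    s3_loo = fva(set_uptake(sc, "EX_o2", loo_sc), config=config).bin_counts["S3"]
    prof_sc = span_profile(sc, config=config)
    prof_ss = span_profile(ss, config=config)
    ok = s3_low > s3_loo and prof_ss.invariance_metric < prof_sc.invariance_metric
    out["span"] = {
        "passed": bool(ok),
        "detail": (
            f"SC S3 at O2=2: {s3_low} vs at line of optimality: {s3_loo}; "
            f"invariance metric SC {prof_sc.invariance_metric:.3f} "
            f"vs SS {prof_ss.invariance_metric:.3f}"
        ),
        "sc_s3_low_o2": int(s3_low),
        "sc_s3_loo": int(s3_loo),
        "sc_invariance_metric": prof_sc.invariance_metric,
        "ss_invariance_metric": prof_ss.invariance_metric,
    }

    # 4. deletion-induced pattern flip
    mutant = apply_deletions(ss, SS_RECYCLING_SET)
    pat_mut = availability_pattern(scan(mutant, config=config))
    ok = (not pat_ss.all_excess_o2_limited) and pat_mut.all_excess_o2_limited
    out["deletion_flip"] = {
        "passed": bool(ok),
        "detail": (
            f"SS minus {'+'.join(SS_RECYCLING_SET)}: excess fraction "
            f"{pat_mut.fraction_excess:.3f} "
            f"(all_excess={pat_mut.all_excess_o2_limited})"
        ),
        "mutant_fraction_excess": pat_mut.fraction_excess,
    }
    return out
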