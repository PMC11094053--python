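"""Reproducibility statistics for every comparison and cardiac parameter.

Bland-Altman bias and limits of agreement, two-way mixed-effects
absolute-agreement ICC, coefficient of variability, Pearson r, and paired
t-tests at the Bonferroni-adjusted threshold (overall alpha 0.05 over four
hypotheses -> 0.0125). Also reports the systematic deviations of the model's
stroke volume and LV mass as percentages of the observer means, and writes
Bland-Altman plots for the model comparison.
"""

from cinefunc import stats as st
from cinefunc.pipeline import stage_function, stage_predict, stage_stats
from common import RESULTS, SCRATCH, STUDY, cohort, trained_model


def main():
    scans, split, labelings = cohort()
    net, _ = trained_model(scans, split, labelings)
    labelings["model"] = stage_predict(STUDY, scans, split, net)
    function_df = stage_function(STUDY, scans, labelings)

    stats_df = stage_stats(STUDY, function_df)
    RESULTS.mkdir(exist_ok=True)
    stats_df.to_csv(RESULTS / "reproducibility_stats.csv", index=False)
    show = stats_df[["comparison", "parameter", "n", "bias", "icc", "icc_band",
                     "cov_percent", "pearson_r", "t_p_value"]].round(4)
    print(show.to_string(index=False))
    print(f"significance threshold (Bonferroni): "
          f"{st.bonferroni_threshold(STUDY.overall_alpha, STUDY.n_hypotheses)}")

    model_rows = stats_df[stats_df.comparison == "observer1_vs_model"]
    obs1 = function_df[function_df.labeling == "observer1"]
    for param in ("SV", "LV mass"):
        bias = float(model_rows[model_rows.parameter == param].bias.iloc[0])
        ref_mean = float(obs1[param].mean())
        dev = st.relative_deviation(bias, ref_mean)
        print(f"model {param} deviation: {abs(bias):.3f} on a mean of "
              f"{ref_mean:.3f} -> {dev:.1f}%")

    fig_dir = SCRATCH / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    a = obs1.set_index("scan")
    b = function_df[function_df.labeling == "model"].set_index("scan")
    common = sorted(set(a.index) & set(b.index))
    for param in ("EF", "LV mass"):
        s = st.PairedSeries(param, a.loc[common, param].to_numpy(),
                            b.loc[common, param].to_numpy())
        st.bland_altman_plot(s, str(fig_dir / f"bland_altman_{param.replace(' ', '_')}.png"))
    print(f"Bland-Altman plots written to {fig_dir}")


if __name__ == "__main__":
    main()
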