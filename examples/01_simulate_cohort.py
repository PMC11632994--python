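"""Generate a registry-like dnMBC cohort and inspect its structure.

Every patient carries a ground-truth log-risk under each of the three
treatment strategies (CW = chemo without surgery, NS = neoadjuvant then
surgery, SC = surgery then chemo), so downstream estimators can be checked
against the truth.
"""

from dnmbc import default_scenario, generate_cohort

scheme, hazard, assign = default_scenario()
cohort = generate_cohort(scheme, hazard, assign, n=3000, seed=1)
df = cohort.df

print(f"{len(df)} patients, factors: {', '.join(scheme.factor_names)}")
print("\narm shares (CW is the bulk arm, as in registry data):")
print(df["arm"].value_counts(normalize=True).round(3).to_string())
print(f"\nevent rate (all-cause): {df['event_os'].mean():.2f}; "
      f"median follow-up time {df['time_months'].median():.0f} months")
print("\nfirst patient, counterfactual log-risks per arm "
      "(lower is better; the gap is the true treatment effect):")
print(df.iloc[0][["true_log_risk_CW", "true_log_risk_NS", "true_log_risk_SC"]]
      .astype(float).round(3).to_string())
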