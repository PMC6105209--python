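{
  "arms.riva.p_inadequate_first": "printed-value",
  "arms.riva.p_inadequate_second": "printed-value",
  "arms.riva.pre_ecv_days": "printed-value",
  "arms.vka.p_inadequate_first": "printed-value",
  "arms.vka.p_inadequate_second": "printed-value",
  "arms.vka.pre_ecv_days": "printed-value",
  "cohort.male_share": "printed-value",
  "cohort.p_score_lt1": "printed-value",
  "cohort.p_score_lt2": "printed-value",
  "cohort.start_age": "printed-value",
  "costs.early_cancel_minutes": "printed-value",
  "costs.informal_hours": "printed-value",
  "costs.inr_home_per_year": "printed-value",
  "costs.inr_mix_home": "printed-value",
  "costs.inr_mix_service": "printed-value",
  "costs.inr_pre_ecv_count": "printed-value",
  "costs.inr_service_per_year": "printed-value",
  "costs.lastminute_factor": "printed-value",
  "costs.symptomatic_share_post": "printed-value",
  "costs.symptomatic_share_pre": "printed-value",
  "ecv.p_success": "printed-value",
  "schedule.*": "printed-value",
  "utilities.mih_disutility": "printed-value",
  "wtp": "printed-value",
  "arms.*.drug_cost_per_day": "synthetic-plausible",
  "costs.acute": "synthetic-plausible",
  "costs.ecv_tariff": "synthetic-plausible",
  "costs.informal_unit_per_hour": "synthetic-plausible",
  "costs.inr_unit_home": "synthetic-plausible",
  "costs.inr_unit_service": "synthetic-plausible",
  "costs.nurse_hourly_wage": "synthetic-plausible",
  "costs.productivity_per_week": "synthetic-plausible",
  "costs.ssr_consult_cost": "synthetic-plausible",
  "costs.weekly": "synthetic-plausible",
  "demographics": "synthetic-plausible",
  "ecv.recurrence_annual_prob": "synthetic-plausible",
  "ecv.ssr_annual_prob": "synthetic-plausible",
  "events.*": "synthetic-plausible",
  "events.mortality": "synthetic-plausible",
  "utilities.*": "synthetic-plausible",
  "utilities.mehra": "synthetic-plausible"
}
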