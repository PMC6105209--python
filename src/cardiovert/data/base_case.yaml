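cohort:
  start_age: 64.4
  male_share:
    mean: 0.74
    se: 0.037
    family: beta
  p_score_lt1: 0.026
  p_score_lt2: 0.127
  cohort_size: 10000
schedule:
  max_attempts: 2
  post_ecv_oac_weeks: 6
  horizon_weeks: 52
arms:
  riva:
    pre_ecv_days: 22
    p_inadequate_first:
      mean: 0.0024
      se: 0.00023999999999999998
      family: beta
    p_inadequate_second:
      mean: 0.0024
      se: 0.00023999999999999998
      family: beta
    drug_cost_per_day:
      mean: 2.269435658243977
      se: 0.0
      family: fixed
    inr_monitored: false
  vka:
    pre_ecv_days: 30
    p_inadequate_first:
      mean: 0.4419
      se: 0.04419000000000001
      family: beta
    p_inadequate_second:
      mean: 0.2
      se: 0.020000000000000004
      family: beta
    drug_cost_per_day:
      mean: 0.1055388818741763
      se: 0.0
      family: fixed
    inr_monitored: true
ecv:
  p_success:
    mean: 0.864
    se: 0.0432
    family: beta
  ssr_annual_prob:
    mean: 0.210095220200023
    se: 0.03151428303000345
    family: beta
  recurrence_annual_prob:
    mean: 0.4499460600594943
    se: 0.06749190900892414
    family: beta
events:
  is_:
    value:
      mean: 0.006265836139212486
      se: 0.0009398754208818728
      family: beta
    kind: prob
  mi:
    value:
      mean: 0.004224068218312291
      se: 0.0006336102327468437
      family: beta
    kind: prob
  ich:
    value:
      mean: 0.0037780010933033217
      se: 0.0005667001639954982
      family: beta
    kind: prob
  mah:
    value:
      mean: 0.016880773164912426
      se: 0.002532115974736864
      family: beta
    kind: prob
  gih:
    value:
      mean: 0.0054349108764007205
      se: 0.000815236631460108
      family: beta
    kind: prob
  mih:
    value:
      mean: 0.1152083650439791
      se: 0.017281254756596864
      family: beta
    kind: prob
  mortality:
  - - 40.0
    - 0.0012
  - - 45.0
    - 0.0019
  - - 50.0
    - 0.003
  - - 55.0
    - 0.0048
  - - 60.0
    - 0.0077
  - - 65.0
    - 0.012
  - - 70.0
    - 0.0195
  - - 75.0
    - 0.034
  - - 80.0
    - 0.061
  - - 85.0
    - 0.112
  - - 90.0
    - 0.195
  - - 95.0
    - 0.31
utilities:
  symptomatic_af:
    mean: 0.6534267884140407
    se: 0.032671339420702036
    family: beta
  asymptomatic_af:
    mean: 0.8137040915942507
    se: 0.04068520457971254
    family: beta
  permanent_af:
    mean: 0.6854822490500828
    se: 0.03427411245250414
    family: beta
  post_is:
    mean: 0.3788172386302273
    se: 0.037881723863022736
    family: beta
  post_mi:
    mean: 0.7342014182586712
    se: 0.07342014182586713
    family: beta
  post_ich:
    mean: 0.4412477745797312
    se: 0.04412477745797312
    family: beta
  mah:
    mean: 0.6138836267861214
    se: 0.06138836267861214
    family: beta
  gih:
    mean: 0.6403916950545234
    se: 0.06403916950545234
    family: beta
  mih_disutility: 0.0
  mehra:
    weights:
      '1': 0.05
      2a: 0.15
      2b: 0.32
      '3': 0.33
      '4': 0.15
    utilities:
      '1': 0.8603436984387939
      2a: 0.798157555979403
      2b: 0.7407938232802925
      '3': 0.6254040371683223
      '4': 0.5286938334399509
costs:
  inr_unit_service:
    mean: 14.314999665223485
    se: 2.147249949783523
    family: gamma
  inr_unit_home:
    mean: 11.06585925584414
    se: 1.659878888376621
    family: gamma
  inr_mix_service: 0.569
  inr_mix_home: 0.431
  inr_pre_ecv_count: 5.5
  inr_service_per_year: 21.1
  inr_home_per_year: 23.5
  ecv_tariff:
    mean: 1293.6806969522447
    se: 194.0521045428367
    family: gamma
  lastminute_factor: 0.5
  nurse_hourly_wage:
    mean: 29.38448409988012
    se: 4.407672614982018
    family: gamma
  early_cancel_minutes: 30.0
  ssr_consult_cost:
    mean: 111.15625021825763
    se: 16.673437532738642
    family: gamma
  acute:
    gih:
      mean: 5799.30048886268
      se: 869.895073329402
      family: gamma
    ich:
      mean: 23249.08498521623
      se: 3487.3627477824343
      family: gamma
    is_:
      mean: 19420.322725338843
      se: 2913.0484088008266
      family: gamma
    mah:
      mean: 3711.79187496909
      se: 556.7687812453635
      family: gamma
    mi:
      mean: 10166.057636217063
      se: 1524.9086454325595
      family: gamma
    mih:
      mean: 126.2244437983757
      se: 18.933666569756355
      family: gamma
  weekly:
    gih:
      mean: 6.745574996166253
      se: 1.011836249424938
      family: gamma
    ich:
      mean: 262.11413039839454
      se: 39.31711955975918
      family: gamma
    is_:
      mean: 217.06929310220758
      se: 32.56039396533114
      family: gamma
    mah:
      mean: 14.646229897201756
      se: 2.196934484580263
      family: gamma
    mi:
      mean: 31.090082451008996
      se: 4.663512367651349
      family: gamma
  productivity_per_week:
    mean: 534.3413024571742
    se: 0.0
    family: fixed
  informal_unit_per_hour:
    mean: 13.032414685041402
    se: 0.0
    family: fixed
  informal_hours:
    nonintensive: 8.0
    intensive: 26.0
  symptomatic_share_pre: 0.7
  symptomatic_share_post: 0.32
wtp: 20000.0
age_sd: 10.8
demographics:
- - 15
  - 20
  - 0.25
  - 14
  - 900
- - 20
  - 25
  - 0.7
  - 28
  - 1900
- - 25
  - 30
  - 0.85
  - 33
  - 2700
- - 30
  - 35
  - 0.86
  - 33
  - 3200
- - 35
  - 40
  - 0.85
  - 33
  - 3500
- - 40
  - 45
  - 0.85
  - 33
  - 3700
- - 45
  - 50
  - 0.84
  - 33
  - 3800
- - 50
  - 55
  - 0.81
  - 33
  - 3800
- - 55
  - 60
  - 0.74
  - 32
  - 3700
- - 60
  - 65
  - 0.52
  - 31
  - 3600
- - 65
  - 67
  - 0.14
  - 25
  - 3300
metadata:
  generator:
    seed: 20201
    preset: base_like
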