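# Theory-driven diabetes specification over the synthetic survey columns.
# Qualitative constraints follow the published meta-analytic consensus:
# disease risk rises with age and BMI, smoking and secondhand smoke are
# harmful, physical activity is protective with a monotone dose response.
# Monotone interaction constraints bound the double increment of the
# interaction surface (see docs/methods.md).
outcome: diabetes
family: binomial
treatment: activity
variables:
  - {name: activity, kind: ordinal, levels: [1, 2, 3, 4], reference_level: 1}
  - {name: age, kind: continuous-discretized, bin_edges: [18, 35, 50, 65, 200]}
  - {name: bmi, kind: continuous-discretized, bin_edges: [0, 22.5, 27.5, 32.5, 100]}
  - {name: smoking, kind: binary}
  - {name: secondhand, kind: binary}
  - {name: gender, kind: binary}
  - {name: alcohol, kind: ordinal, levels: [1, 2, 3]}
  - {name: fruitveg, kind: ordinal, levels: [1, 2, 3]}
  - {name: trust, kind: ordinal, levels: [1, 2, 3]}
  - {name: region, kind: categorical, levels: [1, 2, 3, 4, 5]}
  - {name: income, kind: continuous-linear}
  - {name: education, kind: continuous-linear}
terms:
  - {variables: [activity], monotonicity: decreasing, sign: negative}
  - {variables: [age], monotonicity: increasing, sign: unrestricted}
  - {variables: [bmi], monotonicity: increasing, sign: positive}
  - {variables: [smoking], monotonicity: none, sign: positive}
  - {variables: [secondhand], monotonicity: none, sign: positive}
  - {variables: [gender], monotonicity: none, sign: unrestricted}
  - {variables: [alcohol], monotonicity: none, sign: unrestricted}
  - {variables: [fruitveg], monotonicity: none, sign: unrestricted}
  - {variables: [trust], monotonicity: none, sign: unrestricted}
  - {variables: [region], monotonicity: none, sign: unrestricted}
  - {variables: [income], monotonicity: none, sign: unrestricted}
  - {variables: [education], monotonicity: none, sign: unrestricted}
  # excess BMI risk attenuates with age
  - {variables: [bmi, age], monotonicity: decreasing, sign: negative}
  - {variables: [age, gender], monotonicity: none, sign: unrestricted}
  - {variables: [smoking, gender], monotonicity: none, sign: unrestricted}
  - {variables: [alcohol, gender], monotonicity: none, sign: unrestricted}
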