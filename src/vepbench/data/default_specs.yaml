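# Threshold specs for the three synthetic demo tools.
# Rules are authored on each tool's native scale; comparators are part of
# the spec, never a global convention.
- tool_name: metaA
  spec_name: metaA_a
  direction: higher_is_deleterious
  tol_rule: {comparator: "<", cutoff: 0.4}
  del_rule: {comparator: ">", cutoff: 0.7}
- tool_name: metaA
  spec_name: metaA_b
  direction: higher_is_deleterious
  tol_rule: {comparator: "<=", cutoff: 0.7}
  del_rule: {comparator: ">", cutoff: 0.7}
- tool_name: metaA
  spec_name: metaA_c
  direction: higher_is_deleterious
  tol_rule: {comparator: "<=", cutoff: 0.5}
  del_rule: {comparator: ">", cutoff: 0.5}
- tool_name: lowB
  spec_name: lowB_a
  direction: lower_is_deleterious
  del_rule: {comparator: "<=", cutoff: 0.35}
  tol_rule: {comparator: ">", cutoff: 0.35}
- tool_name: lowB
  spec_name: lowB_b
  direction: lower_is_deleterious
  del_rule: {comparator: "<=", cutoff: 0.25}
  tol_rule: {comparator: ">=", cutoff: 0.45}
- tool_name: catC
  spec_name: catC_a
  categorical_map: {D: DEL, T: TOL}
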