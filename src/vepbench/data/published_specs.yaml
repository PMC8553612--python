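# Published tool-threshold combinations for real score tables.
# Only combinations whose boundaries are stated in the primary literature's
# main text are encoded here; supply your own file for a fuller panel.
- tool_name: REVEL
  spec_name: Revel_a
  direction: higher_is_deleterious
  tol_rule: {comparator: "<", cutoff: 0.4}
  del_rule: {comparator: ">", cutoff: 0.7}
- tool_name: REVEL
  spec_name: Revel_b
  direction: higher_is_deleterious
  tol_rule: {comparator: "<=", cutoff: 0.7}
  del_rule: {comparator: ">", cutoff: 0.7}
- tool_name: REVEL
  spec_name: Revel_c
  direction: higher_is_deleterious
  tol_rule: {comparator: "<=", cutoff: 0.5}
  del_rule: {comparator: ">", cutoff: 0.5}
- tool_name: Meta-SNP
  spec_name: MetaSNP_a
  direction: higher_is_deleterious
  tol_rule: {comparator: "<=", cutoff: 0.5}
  del_rule: {comparator: ">", cutoff: 0.5}
- tool_name: Eigen-PC
  spec_name: EigenPC_b
  direction: higher_is_deleterious
  tol_rule: {comparator: "<", cutoff: 0.0}
  del_rule: {comparator: ">", cutoff: 0.5}
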