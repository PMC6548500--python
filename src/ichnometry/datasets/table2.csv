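footprint_id,side,length_appearance,width_appearance,toe_formula,toes_region,toe_one_position,ball_region,arch_medial,arch_lateral,heel_shape,heel_posterior,morphotype
SM3,R,short,broad,"1, 2, ?",short - broad,"extended, anteriorly",,straight,concave,circular,convex pronounced,1
SM4,L,,,"1,2,3,4,5",short - broad,"extended, anteriorly",short - moderate,,concave,,,1
SM43,L,short,broad,"1,2, ?",short - broad,"extended, anteriorly",,straight,convex,,convex pronounced,1
SM17,R,short,broad,"1,2,3,4,5",short - broad,"extended, anteriorly",,straight/concave,convex,,convex pronounced,1
SM5,R,moderate,moderate,"1,2,3,4,5",short - broad,extended oblique medially,long - moderate,concave,concave,,convex slight,2
SM42,R,moderate,,"1,2, ?",,extended oblique medially,,concave,,,convex pronounced,2
SM26,L,moderate,broad,"1,2,3,4,5",short - moderate,extended oblique laterally,,concave,concave,,convex slight,2
CA8,R,long,moderate,"1,2,3,4,5",moderate - broad,extended oblique medially,long - moderate,concave,straight,oblong,convex pronounced,3
CA10,R,long,moderate,"1,2,3,4",moderate - broad,extended oblique medially,,straight/concave,straight,oblong,convex pronounced,3
SM15,L,long,moderate,"2,3,1,4,5",moderate - broad,extended oblique medially,long - narrow,concave,straight,oblong,convex pronounced,3
SM11,R,long,moderate,"1,2,3,4,5",short - broad,extended anteriorly,,straight/concave,convex,oblong,convex pronounced,3
SM6,L,long,moderate,"2,1,3,4,5",short - broad,flexed slight,long - narrow,concave,convex,oblong,convex pronounced,3
SM1,L,long,moderate,"2,3,1,4,5",short - broad,extended oblique medially,moderate - narrow,unknown,convex,circular,convex pronounced,3
C33,L,long,broad,"1,2,3,4,5",long - broad,extended oblique medially,long - broad,concave,convex,oblong,convex pronounced,3
C36,L,long,very narrow,"1,2,3,4,5",moderate - narrow,extended oblique laterally,long - narrow,concave,straight,oblong,convex pronounced,3
CA1,R,long,,"1,2,3,4",moderate - broad,extended anteriorly,moderate - narrow,straight,,oblong,"convex, pronunced",4
CA2,L,long,moderate,"1,2,3,4,5",moderate - broad,extended anteriorly,moderate - narrow,concave,straight,oblong,convex pronunced,4
C61,L,long,moderate,"1,2,3,4,5",moderate - broad,extended oblique medially,moderate - narrow,straight/concave,straight/convex,oblong,convex pronunced,4
C63,R,long,moderate,"1,2,3,4,5",moderate - broad,extended anteriorly,moderate - narrow,straight/concave,straight/concave,oblong,convex pronunced,4
M21,R,long,moderate,"1,2,3,4,5",moderate - broad,extended anteriorly,moderate - narrow,concave,straight,oblong,convex pronunced,4
C9,R,long,moderate,1,,extended anteriorly,moderate - narrow,straight,convex,oblong,convex pronunced,4
C44b,L,long,broad,"2,1,3,4,5",short - broad,extended oblique medially,moderate - broad,concave,convex,oblong,"convex, moderate",4
C60,L,long,broad,"1,2,3,4,5",moderate - broad,extended oblique laterally,moderate - broad,straight/concave,straight/concave,circular,convex moderate,5
C37,L,long,broad,"1,2,3,4,5",moderate - broad,extended anteriorly,moderate - broad,straight/concave,straight/concave,circular,convex moderate,5
C35b,R,long,broad,"1,2,3,4,5",moderate - broad,extended anteriorly,moderate - broad,,straight/concave,circular,convex moderate,5
C44,L,long,broad,"1,2,3,4,5",moderate - broad,extended anteriorly,moderate - broad,concave,straight/concave,oblong,convex pronunced,5
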