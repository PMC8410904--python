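# Detection plans for the synthetic skull-phantom landmarks.
# proto_ans sits on the anterior bone surface (single-stage works: two
# coordinates from the anterior view, depth from the bone boundary along
# the pixel ray).  proto_sella is a cavity centre and proto_foramen a
# canal point in empty space, so they have no single-stage plan.
- {landmark: proto_ans, name: proto_ans_single, type: 2, mode: single, stages: [av]}
- {landmark: proto_ans, name: proto_ans_two_stage, type: 2, mode: two_stage, stages: [av, sclv]}
- {landmark: proto_sella, name: proto_sella_two_stage, type: 2, mode: two_stage, stages: [sclv, actv]}
- {landmark: proto_foramen, name: proto_foramen_two_stage, type: 3, mode: two_stage, stages: [bv, sclv]}
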