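# Detection plans for the 16 clinical craniofacial landmarks.
# View codes: tv/bv top/bottom, av/pv anterior/posterior, rv/lv lateral,
# scrv/sclv sagittal-cut lateral, actv/acbv axial-cut top/bottom,
# ccpv coronal-cut posterior.  Stage order is coarse global view first,
# cutaway views positioned from earlier predictions after.
# The image-axis -> world-axis readout of every view is fixed by the view
# geometry (lateral views read y/z, frontal views x/z, axial views x/y).
- {landmark: bregma, type: 1, mode: single, stages: [tv]}
- {landmark: sella, type: 2, mode: two_stage, stages: [sclv, actv]}
- {landmark: cfm, type: 3, mode: two_stage, stages: [sclv, acbv]}
- {landmark: nasion, type: 1, mode: two_stage, stages: [av, sclv]}
- {landmark: ans, type: 2, mode: two_stage, stages: [lv, av]}
- {landmark: pogonion, type: 3, mode: two_stage, stages: [av, sclv]}
- {landmark: r_porion, type: 3, mode: two_stage, stages: [rv, ccpv]}
- {landmark: l_porion, type: 3, mode: two_stage, stages: [lv, ccpv]}
- {landmark: r_mf, type: 2, mode: two_stage, stages: [av, actv]}
- {landmark: l_mf, type: 2, mode: two_stage, stages: [av, actv]}
- {landmark: r_f, type: 3, mode: two_stage, stages: [scrv, ccpv]}
- {landmark: l_f, type: 3, mode: two_stage, stages: [sclv, ccpv]}
- {landmark: r_orbitale, type: 2, mode: two_stage, stages: [av, sclv]}
- {landmark: l_orbitale, type: 2, mode: two_stage, stages: [av, scrv]}
- {landmark: r_iof, type: 2, mode: three_stage, stages: [av, sclv, actv]}
- {landmark: l_iof, type: 2, mode: three_stage, stages: [av, scrv, actv]}
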