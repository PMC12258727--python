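category	keywords
protein aggregation & membrane stability	dehydrin|late embryogenesis|LEA|annexin|remorin|ABA-inducible|cold-regulated|COR protein
protein folding & chaperone activity	heat shock|chaperon|HSP|peptidyl-prolyl|protein disulfide isomerase|GO:0006457|GO:0051082
metabolism & osmoregulation	malate synthase|aldose reductase|sucrose synthase|invertase|trehalose|galactinol|raffinose|proline|betaine|fructan|GO:0006970
detoxification & ROS scavenging	glutathione|peroxidase|catalase|superoxide dismutase|aldo-keto|thioredoxin|glutaredoxin|ascorbate|GO:0098869
lipid metabolism	lipid transfer|lipase|phospholipase|fatty acid|desaturase|phosphatidylethanolamine-binding|phospholipid-binding|oleosin|GO:0006629
antifreeze & cell wall modification	antifreeze|chitinase|thaumatin|zeamatin|xyloglucan|expansin|pectin|glucanase|GO:0071555
cold signal transduction	calmodulin|EF-hand|calcium-binding|14-3-3|protein kinase|phosphatase 2C|CBF|DREB|GO:0009409
cytoskeletal organization	actin|tubulin|microtubule|profilin|villin|kinesin|myosin|GO:0007010
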