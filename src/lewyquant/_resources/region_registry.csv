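region,cluster,n_annotations
middle_frontal_gyrus,cortical,1
sulcus_of_middle_frontal_gyrus,cortical,1
cingulate_gyrus,cortical,1
sulcus_between_cingulate_and_frontal_gyrus,cortical,1
insular_gyrus,cortical,1
claustrum,subcortical,1
putamen,subcortical,1
superior_temporal_gyrus,cortical,1
sulcus_between_superior_and_middle_temporal_gyrus,cortical,1
middle_temporal_gyrus,cortical,1
amygdala,amygdala_entorhinal,1
entorhinal_cortex,amygdala_entorhinal,1
parietal_gyrus,cortical,1
medial_thalamus,subcortical,1
lateral_thalamus,subcortical,1
substantia_nigra,brainstem,2
ca4,hippocampal,1
ca3,hippocampal,1
ca2,hippocampal,1
ca1,hippocampal,1
subiculum,hippocampal,1
parahippocampal_gyrus,cortical,1
striate_area_gyrus,cortical,1
striate_area_sulcus,cortical,1
cerebellar_cortex,subcortical,1
dentate_nucleus,subcortical,1
locus_coeruleus,brainstem,2
olfactory_bulb,unassigned,1
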