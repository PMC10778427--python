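patient,sex,age,diagnosis,group,n_necrosis,n_enhancing,n_nonenhancing
1,M,56,Oligodendroglioma (grade 2),glioma,0,0,4
2,F,74,Astrocytoma (grade 2),glioma,0,0,4
3,F,52,Brain metastasis (lung carcinoma),metastasis,0,2,0
4,M,57,Brain metastasis (adenocarcinoma),metastasis,2,1,0
5,M,72,Brain metastasis (adenocarcinoma),metastasis,0,0,2
6,F,40,Oligodendroglioma (grade 3),glioma,0,2,1
7,F,78,Brain metastasis (adenocarcinoma),metastasis,0,3,0
8,M,75,Glioblastoma (grade 4),glioma,3,1,0
9,F,68,Brain metastasis (melanoma),metastasis,1,3,0
10,M,75,Glioblastoma (grade 4),glioma,2,2,0
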