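>IGKV1-5*01 synthetic stand-in kappa germline V gene
DIQMTQSPSSLSASVGDRVTITCRASQSISSYLNWYQQKPGKAPKLLIYAASSLQSGVPS
RFSGSGSGTEFTLTISSLQPEDFATYYCQQ
>IGKV1-39*01 synthetic stand-in kappa germline V gene
DIQMTQSPDSLSASVGDRVTITCRASQDVSTAVAWYQQKPGKAPKLLIYSASFLYSGVPS
RFSGSGSGTDYTLTISSLQPEDFATYYCQQ
>IGKV3-20*01 synthetic stand-in kappa germline V gene
EIVLTQSPGTLSLSPGERATLSCRASQSVSSSYLWYQQKPGQAPRLLIYGASSRATGIPD
RFSGSGSGTDFTLTISRLEPEDFATYYCQQ
>IGKV1-33*01 synthetic stand-in kappa germline V gene
DIQMTQSPSSLSASVGDRVTITCQASQDINNYLNWYQQKPGKAPRLLIYDASNLETGVPS
RFSSSGSGTDFTLTISSLQPEDFATYYCQQ
>IGKV2-28*01 synthetic stand-in kappa germline V gene
DIVMTQSPLSLPVTPGEPASISCRSSQSLLHSNGYNYLDWYLQKPGQSPQLLIYLGSNRA
SGVPDRFSGSGSGTDFTLKISRVEAEDVATYYCQQ
>IGKV4-1*01 synthetic stand-in kappa germline V gene
DVVMTQSPDSLAVSLGERATINCKSSQSVLYSSNNKNYLAWYQQKPGQPPKLLIYWASTR
ESGVPDRFSGSGSGTDFTLTISSLQAEDVATYYCQQ
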