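>IGHV1-46*01 synthetic stand-in heavy germline V gene
QVQLVQSGAEVKKPGASVKVSCKASGYTFTSYYMHWVRQAPGQGLEWMGIINPSGGSTSY
AQKFQRVTITRDTSTSTVYMELSSSLRSEDTACARAR
>IGHV1-2*01 synthetic stand-in heavy germline V gene
QVQLVQSGAEVKKPGASVKVSCKVSGYTFTGYYMHWVRQAPGKGLEWMGWINPNSGGTNY
AQKFQRVTITRDTSTNTVYMELSSSVRSEDTACARAR
>IGHV1-69*01 synthetic stand-in heavy germline V gene
QVQLVQSGAEVKKPGSSVKVSCKASGFTFTNYAMSWVRQAPGQGLEWMGVISYDGSNKYY
ADSVKRVTITRDTTTSTVYMELSSSLRSEDTACARAR
>IGHV3-23*01 synthetic stand-in heavy germline V gene
EVQLLESGGGLVQPGGSLRLSCAASGFTFSSYAMSWVRQAPGKGLEWVSAISGSGGSTYY
ADSVKRFTISRDNSKNTLYLQMNSLRAEDTACARAR
>IGHV4-59*01 synthetic stand-in heavy germline V gene
QVQLQESGPGLVKPSETLSLTCTVSGYSISSGYYWSWIRQPPGKGLEWIGYIYYSGSTNY
NPSLKSRVTISVDTSKNQFSLKLSSVTAADTACARAR
>IGHV5-51*01 synthetic stand-in heavy germline V gene
EVQLVQSGAEVKKPGESLKISCKGSGYSFTSYWIGWVRQMPGKGLEWMGIIYPGDSDTRY
SPSFQQVTISRDKSISTVYLQWSSLKASDTACARAR
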