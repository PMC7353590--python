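>IGHG1_CH1_fragment human IgG1 heavy constant region fragment
ASTKGPSVFPLAPSSKSTSGGTAALGCLVKDYFPEPVTVSWNSGALTSGVHTFPAVLQSS
GLYSLSSVVTVPSSSLGTQTYICNVNHKPSNTKVDKKVEPKSC
>IGHG2_CH1_fragment human IgG2 heavy constant region fragment
ASTKGPSVFPLAPCSRSTSESTAALGCLVKDYFPEPVTVSWNSGALTSGVHTFPAVLQSS
GLYSLSSVVTVPSSNFGTQTYTCNVDHKPSNTKVDKTVERK
>P01602 synthetic carrier of DIQMTQSPSTLSASVGDR
MDIQMTQSPSTLSASVGDRVTITCQASQDISNYLNWYQQKPGQAPR
>A0A0B4J1V2 synthetic carrier of SRLTISK
MGWSLILLFLVAVATGVHSRSRLTISKDNAKNTVYLQMNSLR
>Q07020 synthetic carrier of NQVVLK
MGRVIPVLLLVLLSLEVSGNQVVLKEYALFKAIDDK
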