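construct	loop_A	loop_B	loop_C	loop_D	loop_E
WT	HILSGGSHGMFLTV	SGGHINPTVTFSLCLLGREPWRKFP	FATYPSKHLTLL	IVDPYNNPIPQGLEA	AVNPARDLGPRIFTAIAG
H53A	HILSGGSAGMFLTV	SGGHINPTVTFSLCLLGREPWRKFP	FATYPSKHLTLL	IVDPYNNPIPQGLEA	AVNPARDLGPRIFTAIAG
G54A	HILSGGSHAMFLTV	SGGHINPTVTFSLCLLGREPWRKFP	FATYPSKHLTLL	IVDPYNNPIPQGLEA	AVNPARDLGPRIFTAIAG
H53A/G54H	HILSGGSAHMFLTV	SGGHINPTVTFSLCLLGREPWRKFP	FATYPSKHLTLL	IVDPYNNPIPQGLEA	AVNPARDLGPRIFTAIAG
H53A/G54H/T85A	HILSGGSAHMFLTV	SGGHINPAVTFSLCLLGREPWRKFP	FATYPSKHLTLL	IVDPYNNPIPQGLEA	AVNPARDLGPRIFTAIAG
T85A	HILSGGSHGMFLTV	SGGHINPAVTFSLCLLGREPWRKFP	FATYPSKHLTLL	IVDPYNNPIPQGLEA	AVNPARDLGPRIFTAIAG
R95A	HILSGGSHGMFLTV	SGGHINPTVTFSLCLLGAEPWRKFP	FATYPSKHLTLL	IVDPYNNPIPQGLEA	AVNPARDLGPRIFTAIAG
E96A	HILSGGSHGMFLTV	SGGHINPTVTFSLCLLGRAPWRKFP	FATYPSKHLTLL	IVDPYNNPIPQGLEA	AVNPARDLGPRIFTAIAG
R99A	HILSGGSHGMFLTV	SGGHINPTVTFSLCLLGREPWAKFP	FATYPSKHLTLL	IVDPYNNPIPQGLEA	AVNPARDLGPRIFTAIAG
H154A	HILSGGSHGMFLTV	SGGHINPTVTFSLCLLGREPWRKFP	FATYPSKALTLL	IVDPYNNPIPQGLEA	AVNPARDLGPRIFTAIAG
G54H/H154A	HILSGGSHHMFLTV	SGGHINPTVTFSLCLLGREPWRKFP	FATYPSKALTLL	IVDPYNNPIPQGLEA	AVNPARDLGPRIFTAIAG
H53A/H154A	HILSGGSAGMFLTV	SGGHINPTVTFSLCLLGREPWRKFP	FATYPSKALTLL	IVDPYNNPIPQGLEA	AVNPARDLGPRIFTAIAG
H53A/G54H/H154A	HILSGGSAHMFLTV	SGGHINPTVTFSLCLLGREPWRKFP	FATYPSKALTLL	IVDPYNNPIPQGLEA	AVNPARDLGPRIFTAIAG
A217T	HILSGGSHGMFLTV	SGGHINPTVTFSLCLLGREPWRKFP	FATYPSKHLTLL	IVDPYNNPIPQGLEA	AVNPTRDLGPRIFTAIAG
T85A/A217T	HILSGGSHGMFLTV	SGGHINPAVTFSLCLLGREPWRKFP	FATYPSKHLTLL	IVDPYNNPIPQGLEA	AVNPTRDLGPRIFTAIAG
Y182A	HILSGGSHGMFLTV	SGGHINPTVTFSLCLLGREPWRKFP	FATYPSKHLTLL	IVDPANNPIPQGLEA	AVNPARDLGPRIFTAIAG
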