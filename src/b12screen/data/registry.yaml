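version: '1'
domain_models:
  PF08267: KKFMKSFDNRGNGKITFNNNTCECIFGGGQHKGVEK
  PF01717: EINTVIEDMNHNYFMDSNFAEIYYDCVPDEMWGQDI
  PF02574: KTMYYLHMTPHPGKTETTDNSFLYPQAELDFDWLSS
  PF00809: IWLVWDFMTPGMQTKGFGERLCHYHNLSQDLCLDCR
  PF02607: SWCPSIVKAHYQRLEKKFVEDKINRCACGVLAINMF
  PF02310: GWYYAPYVFMWCMPRRVAIDEGCYWMRKSGHRECVQ
  PF02965: DPFNHRGTGIFNMWWGKICKYDHEPNGDGDMIYKLY
  PF00258: RKTYISDRWYLAANGYNLMWCVVTVAWLRSCHMQYC
  PF00667: IINRVQPGQWQKEIRTGYYNICPTCWYKQDQWLNAV
  PF00175: DHWHLCHIFEFISVIDYWATVKINCNQHMKSNMLVT
  PF01642: AHSGARRCLQERSVCHYVIPNECSPRKFEIESAVSN
  PF00317: QDFDKFWWKVYRETSSYHKWGWSYVWSNSNGSKQEP
  PF02867: VHHMCYTQHVCTYFTSNTHWGKHNTEGNPKSACQPV
  PF03308: FNACNNRAPGYCIGDWNEQIASWHFCGWRSQSGIRA
  PF01923: TQNCFKAVFMYGYANRSTMQWWNGEKPDDYSHERQH
  PF16882: ANRASCADFYTHLLFWHYLYQNLIMTSTAQKKVMMC
  PF11775: GSCWQLSMGQWWSPCPGIISDDRFRVPFWGHTLQCA
  PF04791: KREHRWASHKPYYPQWPHDDGLTTYTDGCGIQWPHP
  PF01344: AYGDHNEGSMSANDPVAQDIRRHIPAKFDCDQKGCS
families:
- name: METE
  special_rule: mete_arabidopsis
  required_domains:
  - PF08267
  - PF01717
  seeds:
  - id: METE_Creinhardtii
    sequence: WSPYMVFEEWDQSVTDFADNCDEVKKFMKSFDKRGNGKITFWNNTMECIFGGGLHKGVEKRWFRLIWMQPDEWNQFPPSMPVNAEINTVIEDMNHNYFMDSNFAEIYYDCVPDEMWGQDIGQQYTMMYGVTNFANTRDVMMVIA
  - id: METE_Egracilis
    sequence: VSPAMVLEEMDRVVTDMNANNDENKKFMKSFDNRGNGKITFNNNTCECIFGGGQHKGVEKRWFRCPTTQMDEWNQMPPSMPWNFEINTVIEDMNHNYLMDSNFAEITYDCVPDEMWGQDIMQYYTMMYGVTNFANTRDVMMHIH
- name: METH
  special_rule: none
  required_domains:
  - PF02574
  - PF00809
  - PF02607
  - PF02310
  - PF02965
  seeds:
  - id: METH_Creinhardtii
    sequence: PHLICKLVFLHRFLETKHQPRWDNETMYYLHMTPHHGKTETTYNSSLYPQAELDFDWLSSVTWNIAMKKVGCCWDSALRSNDLAIWLVLDFMTPGMQTKGFGERLCHYHNLSQDLCLDCRICNGTCTRFWRDQWYGVLHHCCTKSSCPSIVKAHYQRLVKKFVEDKINRCACGVLAINMFGVLQHLRVSGLHHHTDCPYACPVSGWYYAPYVFMACMPRRQAITEGCYWMRKSGHRECVQTFIFADKMSNVLMDLCAIPDWARKLHFNHRGTGIFNMWWGKICKYDHEPNGDGDNIYKLYPWSVINNQVWHTYYHNDVLDYLIQ
  - id: METH_Hsapiens
    sequence: PHLNCALVFLTSFLKTKHQQDWDNKTMYYLHMTYHIGKTETTDNSFLYPQIELDFDMLSSLTWNIWDKKVGCCWDHNLRPHDCAIWLVTDFMTPGMQTKGFGERLCHYHNLSQDLCLDCRICNGGCTAFWRDQWYGVLHHCCEKSWCPSIVKAHYQRLEKKFVEDKINRCACGVLAINMFWVAQLLRQSGLHHHNACPYACPVSGWYYAPYVDMWCMPRRVAIDEGCAWMRSSGHRECVVTFIVADKMSEVLMDLCAILSTERKDPFNHRGTGTFNMWWGKICKYMHEPDGDGDMIYKLYWKSCINNQRPTPYYHNDVLDYLNQ
- name: MTRR
  special_rule: none
  required_domains:
  - PF00258
  - PF00667
  - PF00175
  seeds:
  - id: MTRR_Creinhardtii
    sequence: DFIVLSRIQLQMMGFNTMHSNTLARKTYISDVWYYAANGYNLMWCVVTVMWLRSCHMQYCDVVAGPFFGYDPHNPQLLALCCWLIINRVQPGQWCKEIRTGYHNICPTCWYKQDQWLNAVPLGVCQPATGMSIGSCLSRWTRQIDHWHLCHIFEFISVIDRWATVKTNCNQHMKSNWLVTFPGQPDFYNDQVQTESPSKRPKEH
  - id: MTRR_Hsapiens
    sequence: EFIKLSRIQDQDMGFNTQHSNTLSRKTYISYRWYLAANGYNLAWCVVTVAWLRSCHTQYCDVVIIPFFDDNPHLEQLSALCCWMIINRVQIGQWQKEIRTGYYNICPTCRYKQDQWLNAVDGGTCIPATGGSIGSNLSCWNYQIDHWHLCHIFEFISVIDYWATVKINCNQHMKSNGLVTFPGQPDCSWDQVQTESPSKRISEH
- name: MCM
  special_rule: none
  required_domains:
  - PF01642
  - PF02310
  seeds:
  - id: MCM_Creinhardtii
    sequence: EKRIMHMHKNPATANPCLQNVEFDDHSGARRCVQERSVCHYVIPNENSPRKGHIEHAVSNMTKVSNSAMKLWSVPVWMNHNPQHGWYYAPSVFMWCMPRRVAIDEGCRWMRKSGHREWVQKLCRYAVWFLVQSQTIPSMCDICE
  - id: MCM_Hsapiens
    sequence: EKFIMSMHKMPATATPKAHSVEFGAHSGARRCLQERSVCHYVIPNECSPRKFEIESAVSNMTHVSNSAMKKWSVPVWENHQPQHGWYYAPYVFMWCMPRRVLIDEGCYWMRKSGHRECVQKLCEYAQWFLHYSQTIQSMQTICL
- name: RNR-II
  special_rule: none
  required_domains:
  - PF00317
  - PF02867
  seeds:
  - id: RNR-II_Creinhardtii
    sequence: CYYCGTTGKKKCQGQFIYQLLNIYQDFDKIWWKVYRETSSYHKWGWSYVWSNSNGSKQEPYWALQGTHYETCTLCAQGNNEEGKVHHMCYTQHVCTYFTSNTHWGKHNTEGNPKWCCQPVHSRNFWDTWPPNVGRSYRRKYYQH
  - id: RNR-II_Hsapiens
    sequence: CYGCGTTGSKTKPGQFSYQLLNIYQDFDKFWWKVYRETSSYHKWGATYVWCNSNGSKQEPYWALAWTRYETCTLCMGYNNEEGKVHHMCLTQHVCTYFTSNTHWGKHNTEGNPKSACQPVHSRCGGDTWPPNVGMSYRRKYYQH
- name: CblA
  special_rule: none
  required_domains:
  - PF03308
  seeds:
  - id: CblA_Creinhardtii
    sequence: VNYQIGWWRSACTECWTGFVTGILLNACNNRAPGYCIGDWDEKIASWHFCGWRSQSGIRASPRLLSEDEVEFQLTHFCFSEDRY
  - id: CblA_Hsapiens
    sequence: VRSQIGWYRSARTECETGFVWGILFNATNNRAPGYCIGDWNEQIATWHKCGWRSQSGIRASPRLLSEKEVHFWLTHFMFNEDRY
- name: CblB
  special_rule: none
  required_domains:
  - PF01923
  seeds:
  - id: CblB_Creinhardtii
    sequence: QTKMNQSFYFQNTDCRQVSSVHFPTQNCFKAVFILGYANRSTMQWPNGEKPDDYSHERPEKFFAIDQENQAYGMTVFDFLWNPM
  - id: CblB_Hsapiens
    sequence: QTKMNQSFYFQNHDCNQVGKVHFPTQNCFKCSFMYGYANRSTYQWWNGEKVDDYSHERQHYFFAIDQINQAYGKTVFPFLWNDM
- name: CblC
  special_rule: none
  required_domains:
  - PF16882
  seeds:
  - id: CblC_Creinhardtii
    sequence: MVAYAKDKVYHGYKCYRIQNGVGNANRMSFADFYTHLLIWHYLYQNLIATSTAQKHVMMCKGMMHKYFFWAKGECEHMYIDYEF
  - id: CblC_Hsapiens
    sequence: MVAYAKIIVYHGYKCYRIQIGVGNANRASGADFYTHLLFWHYLYQNLIMTSTAQKKVMMCKHFMHKYFFWAKGECNHEEIDYEC
- name: CblD
  special_rule: none
  required_domains:
  - PF11775
  seeds:
  - id: CblD_Creinhardtii
    sequence: ITLCMMHMRPTSGANECKVMRVYDGSCWQLSMGQWWSPCPGIESDDRFRVPFWGHTLQCYHRENPITIAPERTKHVIEFEAKAG
  - id: CblD_Hsapiens
    sequence: ITLCMMHMRPTSGAFDPKLMDDIDGSCWQLSMGQWWSDCPGIISDDRFRVPFWGHTLQCNLRENPIMIDPTRTKHVIEFYAKAG
- name: CblF
  special_rule: none
  required_domains:
  - PF04791
  seeds:
  - id: CblF_Creinhardtii
    sequence: MAFPTCMIAYCWKCIGKQIRRHNIKREHRRASHKPYYPQWPHDDGLTTYTDGCGIQWPHPHSPTENNYFAWDPPWIDSPYATTC
  - id: CblF_Hsapiens
    sequence: MAQPHDMIAVCKKCIGKQIRRHNIKREHLWASHKPYYPKWPHDDGLTTYTDGCGIQWPHPKPPTEANAKAFGPPNPDSPYATKC
- name: CblJ
  special_rule: none
  required_domains:
  - PF04791
  seeds:
  - id: CblJ_Creinhardtii
    sequence: YMLHRSWTYMCHRAGAMFRFMISDKRTHRWASHKPYYPQWPHDDGLTTYTDGCGIQWPHPKEEADCEHQEAPYAWLIVNFIGVL
  - id: CblJ_Hsapiens
    sequence: YLLHRSWTYLVLNHEEMGRRIFSDKREHRWASHKPYYPQWPMDDGLTTYTDGCGIQKPHPKVEADCEHHEAPWGWLIVKPILVL
- name: CblX
  special_rule: none
  required_domains:
  - PF01344
  seeds:
  - id: CblX_Creinhardtii
    sequence: MEDEFMKEVFPHAKLLFSTAKRGAAYGDHNEGSMSANDPVAQDIRCHIPAKFDCDQKGCSWRPTVITILFWGSEAVYGFKTFQT
  - id: CblX_Hsapiens
    sequence: MEDEFMAEWFLHSKLLFSTAKRGAAYGDHNEGSMSANDPVAQDIRRHIPAKFDCDQKGCSTDTTVITILFIGSEAVTGFKSIQT
- name: epi-CblC
  special_rule: none
  required_domains:
  - PF16882
  seeds:
  - id: epi-CblC_Creinhardtii
    sequence: AKGIYQQMCWCKLESSKKIETESAANRASCADFYTHLLFWHYLYQNLIMTSTAQKKVMMCDFTNEHYEDHQMNFNYQEMDPNWC
  - id: epi-CblC_Hsapiens
    sequence: AKGIYVDMCWCELVSSKKIETESAANRASCADFYTHLLFWHYIYQNLIMTSTAQKKVMMCDFHNEHYEDHKLNWNYMEMTPCWC
- name: CBA1
  special_rule: cba1_consensus
  required_domains: []
  seeds:
  - id: CBA1_Ptricornutum
    sequence: LVCQPFREVQAEMIWICMYWAKMSRFQICYTWSVCRTDGSQCHIKGPWRWSQWWRQLAMGDDGHKHWHSINEACLRGMYICECMLTGIRLYNAVLYTKSDRHIQAGGDFLQNETNGFKDHTMCNHFMIDMLISSFRAWDWHQAFFLQRMGFRLEHNPAVWTGGIGKTKSNHYQCYCIEQNAKVCPMVENQHNELEVWHMYPMARWRLAWCVFYFGTMEQPWFKAHDQIFCFIKQMYQDWPVLLTHREPGQYRMHPSSQQFAVWVECHMRWINEFWNAKNNDGYYTCYPLMGDLPIHQYAW
  - id: CBA1_Creinhardtii
    sequence: LPNQDFHCCYVHDGRAWRARAKMPERQAGYTVKGNRRDRWPRHGNRCARTGHTYQQLNRFDGGIAHWNMINRNGSRKWGKIECMFGEKRLYNQMLQPFWFPPDAWVTTSRAREGTFGCDEWFITCEVYSMLAVVRAHWEWMHEFHPHYRWFRHCHLPEWGTAACWSQTSCWYPCEERSPSKKVDRFVHNDYNELYDWHPYGHHQWDICWDDFSPCTMELLWLFMGGYAGCFSVQDHHIWWVMPNTRSWNQPDPHFSPSDIAVRSEHHHLDIWEFWLMHKRDGYDTCLIWNPTIPIRGQMI
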